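"""Exception hierarchy for cellcarve."""


class CellCarveError(Exception):
    """Base class for all cellcarve errors."""


class InvalidConfigError(CellCarveError):
    """A configuration value violates its contract (e.g. even filter scale)."""


class InvalidInputError(CellCarveError):
    """An input image/map violates its contract (e.g. constant map to Otsu)."""


class NoAttentionWindowsError(CellCarveError):
    """No elliptical attention windows were found; automatic target sizing
    is impossible and the caller must supply an explicit target."""
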