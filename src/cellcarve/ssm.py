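"""Saliency Strength Map: smoothed average of the saliency map and the
EAW distance-transform strength, normalized to [0, 255]."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = ["SmoothingConfig", "build_ssm"]


@dataclass
class SmoothingConfig:
    """Gaussian smoothing of the fused map.

    ``truncate`` is the kernel radius in standard deviations (scipy
    convention), so the half-width in pixels is ``truncate * sigma``.
    """

    sigma: float = 2.0
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidConfigError(f"sigma must be > 0, got {self.sigma}")
        if self.truncate <= 0:
            raise InvalidConfigError(
                f"truncate must be > 0, got {self.truncate}"
            )


def _rescale255(values: np.ndarray, name: str) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        logger.warning("degenerate %s (constant); treated as all-zero", name)
        return np.zeros_like(values, dtype=np.float64)
    return (values - lo) * (255.0 / (hi - lo))


def build_ssm(
    cm: np.ndarray,
    eaw_s: np.ndarray,
    smoothing: SmoothingConfig | None = None,
) -> np.ndarray:
    """Fuse saliency map and EAW strength into the carving energy.

    ``cm`` (any range; rescaled to [0, 255] first so the operands are
    commensurate) and ``eaw_s`` (already [0, 255]) are averaged
    elementwise, Gaussian-smoothed, then min-max normalized to [0, 255].
    """
    cm = np.asarray(cm, dtype=np.float64)
    eaw_s = np.asarray(eaw_s, dtype=np.float64)
    if cm.shape != eaw_s.shape:
        raise InvalidInputError(
            f"shape mismatch: cm {cm.shape} vs eaw_s {eaw_s.shape}"
        )
    smoothing = smoothing or SmoothingConfig()
    fused = 0.5 * (_rescale255(cm, "saliency map") + eaw_s)
    smoothed = ndimage.gaussian_filter(
        fused, sigma=smoothing.sigma, truncate=smoothing.truncate,
        mode="reflect",
    )
    return _rescale255(smoothed, "SSM")
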