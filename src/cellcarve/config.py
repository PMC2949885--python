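"""Pipeline configuration: dataclass, YAML round-trip, and the rule that
rescales size-dependent parameters relative to a reference image size."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .exceptions import InvalidConfigError
from .saliency import SaliencyConfig
from .ssm import SmoothingConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "nearest_odd"]


def nearest_odd(x: float, minimum: int = 3) -> int:
    """Round to the nearest odd integer, at least ``minimum``."""
    return max(int(2 * round((x - 1) / 2) + 1), minimum)


@dataclass
class PipelineConfig:
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    closing_radius: int = 5
    min_region_fraction: float = 0.03
    energy: str = "ssm"                      # "ssm" | "gradient"
    target: tuple[int, int] | None = None    # (H_t, W_t); None = auto
    target_policy: str = "union-span"        # or "projection"
    margin: int = 20
    recompute_every: int = 0                 # 0 = never rebuild the raster
    reference_size: tuple[int, int] = (800, 600)   # (W, H)
    scale_with_size: bool = True

    def __post_init__(self) -> None:
        if self.energy not in ("ssm", "gradient"):
            raise InvalidConfigError(f"unknown energy mode {self.energy!r}")
        if self.target_policy not in ("union-span", "projection"):
            raise InvalidConfigError(
                f"unknown target policy {self.target_policy!r}")
        if self.margin < 0:
            raise InvalidConfigError("margin must be >= 0")
        if not 0 < self.min_region_fraction < 1:
            raise InvalidConfigError("min_region_fraction must be in (0, 1)")

    def scaled_to(self, image_shape: tuple[int, int]) -> "PipelineConfig":
        """Rescale filter scales, closing radius and smoothing sigma
        linearly with image size relative to ``reference_size``."""
        if not self.scale_with_size:
            return self
        h, w = image_shape[:2]
        ref_w, ref_h = self.reference_size
        factor = 0.5 * (w / ref_w + h / ref_h)
        if np.isclose(factor, 1.0):
            return self
        scales = tuple(
            nearest_odd(s * factor) for s in self.saliency.filter_scales)
        return replace(
            self,
            saliency=replace(self.saliency, filter_scales=scales),
            smoothing=replace(
                self.smoothing, sigma=max(self.smoothing.sigma * factor, 0.5)),
            closing_radius=max(int(round(self.closing_radius * factor)), 1),
        )

    def to_dict(self) -> dict:
        return {
            "weights": {
                "color": self.saliency.w_color,
                "orientation": self.saliency.w_orient,
                "saturation": self.saliency.w_sat,
            },
            "filter_scales": list(self.saliency.filter_scales),
            "wavelet": self.saliency.wavelet,
            "reference_size": list(self.reference_size),
            "scale_with_size": self.scale_with_size,
            "closing_radius": self.closing_radius,
            "min_region_fraction": self.min_region_fraction,
            "smoothing_sigma": self.smoothing.sigma,
            "smoothing_truncate": self.smoothing.truncate,
            "energy": self.energy,
            "target": list(self.target) if self.target else None,
            "target_policy": self.target_policy,
            "margin": self.margin,
            "recompute_every": self.recompute_every,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        weights = data.get("weights", {})
        sal = SaliencyConfig(
            filter_scales=tuple(data.get("filter_scales", (11, 13))),
            w_color=weights.get("color", 0.6),
            w_orient=weights.get("orientation", 0.2),
            w_sat=weights.get("saturation", 0.2),
            wavelet=data.get("wavelet", "haar"),
        )
        smoothing = SmoothingConfig(
            sigma=data.get("smoothing_sigma", 2.0),
            truncate=data.get("smoothing_truncate", 4.0),
        )
        target = data.get("target")
        return cls(
            saliency=sal,
            smoothing=smoothing,
            closing_radius=data.get("closing_radius", 5),
            min_region_fraction=data.get("min_region_fraction", 0.03),
            energy=data.get("energy", "ssm"),
            target=tuple(target) if target else None,
            target_policy=data.get("target_policy", "union-span"),
            margin=data.get("margin", 20),
            recompute_every=data.get("recompute_every", 0),
            reference_size=tuple(data.get("reference_size", (800, 600))),
            scale_with_size=data.get("scale_with_size", True),
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
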