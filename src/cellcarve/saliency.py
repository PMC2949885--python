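"""Weighted center-surround saliency map for stained blood-smear images.

The map fuses three half-resolution feature maps -- color opponency
(CIE-Lab a*/b*), local orientation (one-level wavelet detail bands of the
luminance channel) and HSI saturation -- each passed through a
center-surround contrast operator at two square window scales, then
min-max normalized and combined with configurable weights
(default 0.6 color / 0.2 orientation / 0.2 saturation).  The combined map
is up-sampled back to the input resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.transform import resize as _sk_resize

from .exceptions import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

MIN_IMAGE_SIDE = 32

__all__ = [
    "SaliencyConfig",
    "center_surround",
    "compute_color_map",
    "compute_orientation_map",
    "compute_saturation_map",
    "combine_saliency",
    "compute_saliency",
    "haar_level1",
    "hsi_saturation",
]


@dataclass
class SaliencyConfig:
    """Parameters of the saliency stage.

    ``filter_scales`` are odd square window sizes of the center-surround
    operator, calibrated for a reference input size (see
    :class:`cellcarve.config.PipelineConfig` for the size-scaling rule).
    Weights must sum to 1.
    """

    filter_scales: tuple[int, ...] = (11, 13)
    w_color: float = 0.6
    w_orient: float = 0.2
    w_sat: float = 0.2
    wavelet: str = "haar"

    def __post_init__(self) -> None:
        self.filter_scales = tuple(int(s) for s in self.filter_scales)
        for s in self.filter_scales:
            if s < 3 or s % 2 == 0:
                raise InvalidConfigError(
                    f"filter scale {s} must be odd and >= 3"
                )
        if min(self.w_color, self.w_orient, self.w_sat) < 0:
            raise InvalidConfigError("feature weights must be non-negative")
        total = self.w_color + self.w_orient + self.w_sat
        if not np.isclose(total, 1.0):
            raise InvalidConfigError(
                f"feature weights must sum to 1, got {total}"
            )
        if self.wavelet != "haar":
            raise InvalidConfigError(
                f"unsupported wavelet {self.wavelet!r}; only 'haar' is built in"
            )


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check the H x W x 3 contract and return a float copy in [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(
            f"expected an H x W x 3 image, got shape {arr.shape}"
        )
    if arr.shape[0] < MIN_IMAGE_SIDE or arr.shape[1] < MIN_IMAGE_SIDE:
        raise InvalidInputError(
            f"image {arr.shape[:2]} smaller than minimum "
            f"{MIN_IMAGE_SIDE} x {MIN_IMAGE_SIDE}"
        )
    out = arr.astype(np.float64)
    if arr.dtype.kind in "ui" or out.max() > 1.0:
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def center_surround(channel: np.ndarray, scale: int) -> np.ndarray:
    """Per-pixel |center - mean of the s x s surround (center excluded)|.

    Reflect padding at the borders.  Response is non-negative and exactly
    zero on constant inputs.
    """
    chan = np.asarray(channel, dtype=np.float64)
    if chan.ndim != 2:
        raise InvalidInputError("center_surround expects a 2-D channel")
    if scale % 2 == 0 or scale < 3:
        raise InvalidConfigError(f"filter scale {scale} must be odd and >= 3")
    if scale > min(chan.shape):
        raise InvalidConfigError(
            f"filter scale {scale} exceeds channel size {chan.shape}"
        )
    n = scale * scale
    window_mean = ndimage.uniform_filter(chan, size=scale, mode="reflect")
    surround_mean = (window_mean * n - chan) / (n - 1)
    return np.abs(chan - surround_mean)


def _halve(channel: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    return _sk_resize(
        channel, out_shape, order=1, mode="reflect",
        anti_aliasing=False, preserve_range=True,
    )


def _half_shape(image_shape: tuple[int, int]) -> tuple[int, int]:
    return image_shape[0] // 2, image_shape[1] // 2


def compute_color_map(image: np.ndarray, cfg: SaliencyConfig) -> np.ndarray:
    """Mean center-surround contrast of the half-size a* and b* channels.

    Four maps are averaged: channels {a*, b*} x the configured scales.
    """
    rgb = validate_rgb(image)
    lab = rgb2lab(rgb)
    hs = _half_shape(rgb.shape[:2])
    maps = []
    for ci in (1, 2):  # a*, b*
        chan = _halve(lab[..., ci], hs)
        for s in cfg.filter_scales:
            maps.append(center_surround(chan, s))
    return np.mean(maps, axis=0)


def haar_level1(channel: np.ndarray) -> dict[str, np.ndarray]:
    """One-level 2-D Haar decomposition.

    Returns the LL approximation and the LH/HL/HH detail bands, each of
    shape (H//2, W//2); odd trailing rows/columns are dropped.
    """
    chan = np.asarray(channel, dtype=np.float64)
    h2, w2 = chan.shape[0] // 2, chan.shape[1] // 2
    if h2 < 1 or w2 < 1:
        raise InvalidInputError("channel too small for one wavelet level")
    chan = chan[: 2 * h2, : 2 * w2]
    a = chan[0::2, 0::2]
    b = chan[0::2, 1::2]
    c = chan[1::2, 0::2]
    d = chan[1::2, 1::2]
    return {
        "LL": (a + b + c + d) / 2.0,
        "LH": (a + b - c - d) / 2.0,  # horizontal structure
        "HL": (a - b + c - d) / 2.0,  # vertical structure
        "HH": (a - b - c + d) / 2.0,  # diagonal structure
    }


def compute_orientation_map(image: np.ndarray, cfg: SaliencyConfig) -> np.ndarray:
    """Mean center-surround contrast of the three wavelet detail bands.

    Six maps are averaged: bands {HH, HL, LH} x the configured scales.
    The decomposition runs on the CIE-Lab L* channel.
    """
    rgb = validate_rgb(image)
    lab = rgb2lab(rgb)
    bands = haar_level1(lab[..., 0])
    hs = _half_shape(rgb.shape[:2])
    maps = []
    for name in ("HH", "HL", "LH"):
        band = bands[name]
        if band.shape != hs:  # off-by-one from odd input sides
            band = _halve(band, hs)
        for s in cfg.filter_scales:
            maps.append(center_surround(band, s))
    return np.mean(maps, axis=0)


def hsi_saturation(rgb: np.ndarray) -> np.ndarray:
    """Classical HSI saturation: S = 1 - 3 min(R,G,B)/(R+G+B); 0 on black."""
    arr = np.asarray(rgb, dtype=np.float64)
    total = arr.sum(axis=-1)
    sat = np.zeros(arr.shape[:-1])
    nz = total > 0
    sat[nz] = 1.0 - 3.0 * arr[..., :3].min(axis=-1)[nz] / total[nz]
    return np.clip(sat, 0.0, 1.0)


def compute_saturation_map(image: np.ndarray, cfg: SaliencyConfig) -> np.ndarray:
    """Mean center-surround contrast of the half-size HSI saturation channel."""
    rgb = validate_rgb(image)
    sat = _halve(hsi_saturation(rgb), _half_shape(rgb.shape[:2]))
    maps = [center_surround(sat, s) for s in cfg.filter_scales]
    return np.mean(maps, axis=0)


def _minmax01(values: np.ndarray, name: str = "map") -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        logger.warning("degenerate %s (constant); treated as all-zero", name)
        return np.zeros_like(values, dtype=np.float64)
    return (values - lo) / (hi - lo)


def combine_saliency(
    color: np.ndarray,
    orient: np.ndarray,
    sat: np.ndarray,
    cfg: SaliencyConfig,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Min-max normalize each feature map and fuse with the configured
    weights; optionally up-sample (bilinear) to ``out_shape``."""
    if not (color.shape == orient.shape == sat.shape):
        raise InvalidInputError(
            f"feature map shapes differ: {color.shape}, {orient.shape}, "
            f"{sat.shape}"
        )
    cm = (
        cfg.w_color * _minmax01(color, "color map")
        + cfg.w_sat * _minmax01(sat, "saturation map")
        + cfg.w_orient * _minmax01(orient, "orientation map")
    )
    if out_shape is not None and tuple(out_shape) != cm.shape:
        cm = _sk_resize(
            cm, out_shape, order=1, mode="reflect",
            anti_aliasing=False, preserve_range=True,
        )
    return np.clip(cm, 0.0, 1.0)


def compute_saliency(image: np.ndarray, cfg: SaliencyConfig | None = None) -> np.ndarray:
    """Full saliency stage: three feature maps fused and up-sampled to the
    input size.  Returns a float map in [0, 1] of the image's H x W."""
    cfg = cfg or SaliencyConfig()
    color = compute_color_map(image, cfg)
    orient = compute_orientation_map(image, cfg)
    sat = compute_saturation_map(image, cfg)
    return combine_saliency(
        color, orient, sat, cfg, out_shape=np.asarray(image).shape[:2]
    )
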