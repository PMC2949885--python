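"""Elliptical attention windows (EAWs) around nucleus-like salient blobs.

Pipeline: Otsu threshold of the saliency map -> morphological closing to
fill nuclear holes -> removal of small labeled regions (default < 3% of
the image) -> per-region bounding boxes via X-Y projection -> inscribed
ellipses -> Euclidean distance-transform strength ramp inside the ellipse
union, normalized to [0, 255].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

# 8-connectivity for blob labeling, matching the 8-connected seam paths.
_STRUCTURE8 = np.ones((3, 3), dtype=bool)

__all__ = [
    "AttentionWindow",
    "EllipseWindow",
    "otsu_threshold",
    "fill_holes",
    "remove_small_regions",
    "initial_windows",
    "fit_ellipse",
    "eaw_strength",
    "rasterize_ellipses",
    "detect_eaws",
]


@dataclass(frozen=True)
class AttentionWindow:
    """Axis-aligned bounding rectangle of one labeled region.

    ``x``/``y`` are the 0-based column/row of the top-left pixel.
    """

    x: int
    y: int
    width: int
    height: int
    label: int


@dataclass(frozen=True)
class EllipseWindow:
    """Ellipse inscribed in an attention window: center (cx, cy) in
    (col, row) pixels and semi-axes rx (horizontal) / ry (vertical)."""

    cx: float
    cy: float
    rx: float
    ry: float
    parent: AttentionWindow | None = None

    @property
    def label(self) -> int:
        return self.parent.label if self.parent is not None else -1

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "cx": self.cx,
            "cy": self.cy,
            "rx": self.rx,
            "ry": self.ry,
        }


def otsu_threshold(saliency: np.ndarray) -> np.ndarray:
    """Binarize a saliency map at Otsu's between-class-variance optimum.

    Foreground is strictly above the threshold.  Raises on constant maps,
    for which no threshold exists.
    """
    values = np.asarray(saliency, dtype=np.float64)
    if values.size == 0 or values.min() == values.max():
        raise InvalidInputError("cannot threshold a constant saliency map")
    t_op = threshold_otsu(values)
    return values > t_op


def fill_holes(mask: np.ndarray, radius: int = 5) -> np.ndarray:
    """Morphological closing with a disc element; the input is OR-ed back
    in so no foreground pixel is ever lost at the image border."""
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask.copy()
    closed = ndimage.binary_closing(mask, structure=disk(radius).astype(bool))
    return closed | mask


def remove_small_regions(
    mask: np.ndarray, min_fraction: float = 0.03
) -> tuple[np.ndarray, np.ndarray]:
    """Drop 8-connected components with area strictly below
    ``min_fraction`` of the image pixels.

    Returns the cleaned boolean mask and a label image in which surviving
    regions keep consecutive ids 1..n (0 is background).
    """
    mask = np.asarray(mask, dtype=bool)
    if not 0 < min_fraction < 1:
        raise InvalidInputError(f"min_fraction {min_fraction} not in (0, 1)")
    labels, n = ndimage.label(mask, structure=_STRUCTURE8)
    if n == 0:
        return np.zeros_like(mask), labels
    threshold = min_fraction * mask.size
    areas = np.bincount(labels.ravel())[1:]
    keep = areas >= threshold
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    labels = remap[labels]
    return labels > 0, labels


def initial_windows(labels: np.ndarray) -> list[AttentionWindow]:
    """Per-region bounding boxes (the span of each region's nonzero X and
    Y projections), ordered by label."""
    labels = np.asarray(labels)
    windows = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        rows, cols = sl
        windows.append(
            AttentionWindow(
                x=int(cols.start),
                y=int(rows.start),
                width=int(cols.stop - cols.start),
                height=int(rows.stop - rows.start),
                label=lab,
            )
        )
    return windows


def fit_ellipse(
    window: AttentionWindow, shape: tuple[int, int] | None = None
) -> EllipseWindow:
    """Ellipse centered on the window with semi-axes of half its extents,
    clipped so its bounding box stays inside ``shape`` when given."""
    cx = window.x + window.width / 2.0
    cy = window.y + window.height / 2.0
    rx = window.width / 2.0
    ry = window.height / 2.0
    if shape is not None:
        h, w = shape
        rx = max(min(rx, cx, w - cx), 0.5)
        ry = max(min(ry, cy, h - cy), 0.5)
    return EllipseWindow(cx=cx, cy=cy, rx=rx, ry=ry, parent=window)


def rasterize_ellipses(
    eaws: list[EllipseWindow], shape: tuple[int, int]
) -> np.ndarray:
    """Boolean union of the open ellipse interiors on the pixel grid."""
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)
    for e in eaws:
        # restrict work to the bounding box
        r0 = max(int(np.floor(e.cy - e.ry)), 0)
        r1 = min(int(np.ceil(e.cy + e.ry)) + 1, h)
        c0 = max(int(np.floor(e.cx - e.rx)), 0)
        c1 = min(int(np.ceil(e.cx + e.rx)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        dy = (yy[r0:r1, None] - e.cy) / e.ry
        dx = (xx[None, c0:c1] - e.cx) / e.rx
        out[r0:r1, c0:c1] |= dy * dy + dx * dx < 1.0
    return out


def eaw_strength(
    eaws: list[EllipseWindow],
    shape: tuple[int, int],
    normalize: bool = True,
) -> np.ndarray:
    """Euclidean distance-transform ramp inside the union of EAW
    interiors: distance to the nearest non-EAW pixel, zero outside.

    Normalized to [0, 255] unless ``normalize`` is False.
    """
    if not eaws:
        logger.warning("eaw_strength called with no EAWs; returning zeros")
        return np.zeros(shape, dtype=np.float64)
    interior = rasterize_ellipses(eaws, shape)
    strength = ndimage.distance_transform_edt(interior)
    if normalize:
        peak = strength.max()
        if peak > 0:
            strength = strength * (255.0 / peak)
    return strength


def detect_eaws(
    saliency: np.ndarray,
    closing_radius: int = 5,
    min_fraction: float = 0.03,
) -> tuple[list[EllipseWindow], np.ndarray]:
    """Run the full window-extraction chain on a saliency map.

    Returns the EAW list and the cleaned binary mask they came from.
    """
    mask = otsu_threshold(saliency)
    mask = fill_holes(mask, closing_radius)
    mask, labels = remove_small_regions(mask, min_fraction)
    shape = mask.shape
    eaws = [fit_ellipse(w, shape) for w in initial_windows(labels)]
    return eaws, mask
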