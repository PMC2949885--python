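"""Synthetic blood-smear generator with exact nucleus ground truth.

Renders a pale field, pinkish red-cell clutter and near-round purple
nuclei with chromatin-like internal texture (plus optional pale holes),
so the whole detection/carving/metrics stack is testable without any
microscope data.  Generation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import InvalidInputError

__all__ = ["SmearSpec", "GroundTruth", "generate_smear", "degrade"]

# qualitative staining palette: purple nuclei, monotone pink red cells,
# pale near-white background
NUCLEUS_RGB = (120, 60, 150)
RED_CELL_RGB = (232, 182, 188)
BACKGROUND_RGB = (245, 240, 235)
HOLE_RGB = (205, 185, 215)


@dataclass
class SmearSpec:
    """Parameters of one synthetic smear."""

    height: int = 600
    width: int = 800
    n_nuclei: int = 3
    nucleus_radius: tuple[float, float] = (80.0, 100.0)
    ellipticity: tuple[float, float] = (0.85, 1.0)  # ry = rx * factor
    nucleus_rgb: tuple[int, int, int] = NUCLEUS_RGB
    color_jitter: float = 12.0
    texture_sigma: float = 4.0     # chromatin blotch length scale (px)
    texture_amplitude: float = 45.0
    n_holes: int = 2               # pale spots per nucleus
    hole_radius: float = 6.0
    n_red_cells: int = 60
    red_cell_radius: tuple[float, float] = (24.0, 36.0)
    red_cell_rgb: tuple[int, int, int] = RED_CELL_RGB
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    min_gap: float = 40.0          # clearance between nuclei
    border_margin: float = 12.0    # clearance between nucleus and frame
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise InvalidInputError("smear must be at least 32 x 32")
        if self.n_nuclei < 0 or self.n_red_cells < 0:
            raise InvalidInputError("counts must be non-negative")
        if self.nucleus_radius[0] > self.nucleus_radius[1]:
            raise InvalidInputError("nucleus_radius range is inverted")


@dataclass
class GroundTruth:
    """Exact per-nucleus masks and ellipse parameters."""

    masks: list[np.ndarray] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)  # (cy, cx)
    semi_axes: list[tuple[float, float]] = field(default_factory=list)  # (ry, rx)

    def to_dict(self) -> dict:
        return {
            "coordinate_convention": "0-based (row, col)",
            "nuclei": [
                {"label": i + 1, "cy": cy, "cx": cx, "ry": ry, "rx": rx}
                for i, ((cy, cx), (ry, rx)) in enumerate(
                    zip(self.centroids, self.semi_axes))
            ],
        }


def _ellipse_mask(shape, cy, cx, ry, rx):
    h, w = shape
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 < 1.0


def _place_nuclei(spec: SmearSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping nucleus ellipses."""
    placed = []  # (cy, cx, ry, rx)
    for _ in range(spec.n_nuclei):
        for attempt in range(500):
            rx = rng.uniform(*spec.nucleus_radius)
            ry = rx * rng.uniform(*spec.ellipticity)
            r = max(rx, ry)
            lo_x = r + spec.border_margin
            lo_y = r + spec.border_margin
            if lo_x * 2 >= spec.width or lo_y * 2 >= spec.height:
                continue
            cx = rng.uniform(lo_x, spec.width - lo_x)
            cy = rng.uniform(lo_y, spec.height - lo_y)
            ok = all(
                np.hypot(cy - py, cx - px)
                >= r + max(pry, prx) + spec.min_gap
                for py, px, pry, prx in placed
            )
            if ok:
                placed.append((cy, cx, ry, rx))
                break
        else:
            raise InvalidInputError(
                "could not place all nuclei; relax the spec or reseed"
            )
    return placed


def generate_smear(spec: SmearSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one smear and its exact ground truth.

    Painting order: background, red cells (darker rims for faint edges),
    nuclei with chromatin texture and pale holes.  Truth masks cover the
    full ellipse including holes.  Additive noise per ``noise_sigma``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb

    # red-cell clutter: uniform discs with a slightly darker rim
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    for _ in range(spec.n_red_cells):
        r = rng.uniform(*spec.red_cell_radius)
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        body = d2 < r * r
        rim = (d2 < r * r) & (d2 > (r - 2.5) ** 2)
        shade = rng.uniform(-8, 8, size=3)
        img[body] = np.asarray(spec.red_cell_rgb) + shade
        img[rim] = np.asarray(spec.red_cell_rgb) + shade - 12.0

    truth = GroundTruth()
    for cy, cx, ry, rx in _place_nuclei(spec, rng):
        mask = _ellipse_mask((h, w), cy, cx, ry, rx)
        base = np.asarray(spec.nucleus_rgb) + rng.uniform(
            -spec.color_jitter, spec.color_jitter, size=3)
        # chromatin blotches: smoothed noise field modulating each channel
        noise = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), spec.texture_sigma)
        sd = noise[mask].std() or 1.0
        tex = noise / sd * spec.texture_amplitude
        # opponent modulation (R/B up while G down) so the blotches carry
        # chromatic contrast, as stained chromatin does, not just luminance
        for ch, gain in enumerate((1.0, -0.6, 0.7)):
            img[..., ch][mask] = base[ch] + tex[mask] * gain
        for _ in range(spec.n_holes):
            hr = spec.hole_radius
            hy = cy + rng.uniform(-0.5, 0.5) * ry
            hx = cx + rng.uniform(-0.5, 0.5) * rx
            hole = _ellipse_mask((h, w), hy, hx, hr, hr) & mask
            img[hole] = HOLE_RGB
        truth.masks.append(mask)
        truth.centroids.append((float(cy), float(cx)))
        truth.semi_axes.append((float(ry), float(rx)))

    img = np.clip(img, 0, 255).astype(np.uint8)
    if spec.noise_sigma > 0:
        img = degrade(img, spec.noise_sigma,
                      seed=int(rng.integers(0, 2 ** 31)))
    return img, truth


def degrade(image: np.ndarray, noise_sigma: float, seed: int = 0) -> np.ndarray:
    """Add clipped Gaussian pixel noise; ``noise_sigma == 0`` is identity."""
    if noise_sigma < 0:
        raise InvalidInputError("noise sigma must be >= 0")
    img = np.asarray(image)
    if noise_sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noisy = img.astype(np.float64) + rng.normal(0, noise_sigma, img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
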