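"""Forward-energy seam carving driven by an energy raster.

The dynamic program scores each candidate seam step by the intensity
differences the removal would create between newly adjacent pixels
(step costs C_L, C_U, C_R), added to a local term P equal to the L1
gradient magnitude of the energy raster.  Vertical seams are monotone
8-connected top-to-bottom column paths; horizontal seams reuse the same
code path on the transpose.

Border policy: a step-cost difference that references an out-of-range
neighbor contributes 0, and predecessors outside the grid cost +inf.
Ties are broken toward the smallest column index, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .attention import EllipseWindow
from .exceptions import InvalidInputError, NoAttentionWindowsError

try:  # optional fast path; the numpy fallback is exact but slower
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "Seam",
    "CostMatrix",
    "StepCosts",
    "forward_costs",
    "local_energy",
    "build_cost_matrix",
    "find_min_seam",
    "remove_seam",
    "gradient_energy",
    "auto_target_size",
    "resize",
    "replay_seams",
]


@dataclass(frozen=True)
class StepCosts:
    """Forward step costs of the three vertical-seam continuations."""

    cL: float
    cU: float
    cR: float


@dataclass(frozen=True)
class Seam:
    """A monotone 8-connected pixel path spanning the image.

    For a vertical seam, ``path[i]`` is the column removed in row i; for
    a horizontal seam, the row removed in column i.
    """

    orientation: str  # "vertical" | "horizontal"
    path: np.ndarray

    def __post_init__(self) -> None:
        if self.orientation not in ("vertical", "horizontal"):
            raise InvalidInputError(f"bad orientation {self.orientation!r}")
        path = np.asarray(self.path, dtype=np.int64)
        object.__setattr__(self, "path", path)
        if path.size > 1 and np.abs(np.diff(path)).max() > 1:
            raise InvalidInputError("seam path is not 8-connected")

    def to_dict(self) -> dict:
        return {"orientation": self.orientation,
                "path": self.path.tolist()}


@dataclass(frozen=True)
class CostMatrix:
    """Cumulative forward-energy DP table with backpointers in {-1,0,+1}
    (offset of the predecessor column in the row above)."""

    values: np.ndarray
    backpointers: np.ndarray


def forward_costs(ssm: np.ndarray, i: int, j: int) -> StepCosts:
    """Step costs at pixel (i, j); reference scalar implementation.

    cU = |E(i,j+1) - E(i,j-1)|
    cL = cU + |E(i-1,j) - E(i,j-1)|
    cR = cU + |E(i-1,j) - E(i,j+1)|
    with out-of-range differences contributing 0.
    """
    e = np.asarray(ssm, dtype=np.float64)
    h, w = e.shape
    if not (0 <= i < h and 0 <= j < w):
        raise InvalidInputError(f"pixel ({i}, {j}) outside {e.shape}")
    cu = abs(e[i, j + 1] - e[i, j - 1]) if 0 < j < w - 1 else 0.0
    dl = abs(e[i - 1, j] - e[i, j - 1]) if (i > 0 and j > 0) else 0.0
    dr = abs(e[i - 1, j] - e[i, j + 1]) if (i > 0 and j < w - 1) else 0.0
    return StepCosts(cL=cu + dl, cU=cu, cR=cu + dr)


def local_energy(raster: np.ndarray) -> np.ndarray:
    """L1 gradient magnitude |d/dx| + |d/dy| via central differences
    (one-sided at the borders)."""
    e = np.asarray(raster, dtype=np.float64)
    gy = np.gradient(e, axis=0) if e.shape[0] > 1 else np.zeros_like(e)
    gx = np.gradient(e, axis=1) if e.shape[1] > 1 else np.zeros_like(e)
    return np.abs(gx) + np.abs(gy)


@_njit(cache=True)
def _dp_kernel(e, p):  # pragma: no cover - exercised via build_cost_matrix
    h, w = e.shape
    m = np.empty((h, w), np.float64)
    back = np.zeros((h, w), np.int8)
    for j in range(w):
        m[0, j] = p[0, j]
    for i in range(1, h):
        for j in range(w):
            if 0 < j < w - 1:
                cu = abs(e[i, j + 1] - e[i, j - 1])
            else:
                cu = 0.0
            if j > 0:
                best = m[i - 1, j - 1] + cu + abs(e[i - 1, j] - e[i, j - 1])
                bp = -1
                cand = m[i - 1, j] + cu
                if cand < best:
                    best = cand
                    bp = 0
            else:
                best = m[i - 1, j] + cu
                bp = 0
            if j < w - 1:
                cand = m[i - 1, j + 1] + cu + abs(e[i - 1, j] - e[i, j + 1])
                if cand < best:
                    best = cand
                    bp = 1
            m[i, j] = p[i, j] + best
            back[i, j] = bp
    return m, back


def _dp_numpy(e: np.ndarray, p: np.ndarray):
    h, w = e.shape
    m = np.empty((h, w), np.float64)
    back = np.zeros((h, w), np.int8)
    m[0] = p[0]
    cu_all = np.zeros((h, w))
    if w >= 3:
        cu_all[:, 1:-1] = np.abs(e[:, 2:] - e[:, :-2])
    for i in range(1, h):
        prev = m[i - 1]
        cu = cu_all[i]
        cand_l = np.full(w, np.inf)
        cand_l[1:] = prev[:-1] + cu[1:] + np.abs(e[i - 1, 1:] - e[i, :-1])
        cand_u = prev + cu
        cand_r = np.full(w, np.inf)
        cand_r[:-1] = prev[1:] + cu[:-1] + np.abs(e[i - 1, :-1] - e[i, 1:])
        best = cand_l.copy()
        bp = np.full(w, -1, np.int8)
        bp[0] = 0
        best[0] = cand_u[0]
        up_wins = cand_u < best
        best[up_wins] = cand_u[up_wins]
        bp[up_wins] = 0
        right_wins = cand_r < best
        best[right_wins] = cand_r[right_wins]
        bp[right_wins] = 1
        m[i] = p[i] + best
        back[i] = bp
    return m, back


def build_cost_matrix(ssm: np.ndarray, use_numba: bool | None = None) -> CostMatrix:
    """Row-by-row forward-energy DP over the energy raster.

    Row 0 holds the local term P alone; every later entry is
    P(i,j) + min over the three predecessors of (cumulative + step cost).
    """
    e = np.ascontiguousarray(ssm, dtype=np.float64)
    if e.ndim != 2 or e.size == 0:
        raise InvalidInputError("energy raster must be a non-empty 2-D array")
    p = local_energy(e)
    fast = _HAVE_NUMBA if use_numba is None else (use_numba and _HAVE_NUMBA)
    m, back = (_dp_kernel(e, p) if fast else _dp_numpy(e, p))
    return CostMatrix(values=m, backpointers=back)


def find_min_seam(m: CostMatrix, orientation: str = "vertical") -> Seam:
    """Trace the minimum-cost seam from the bottom row upward, taking the
    leftmost argmin and stored backpointers."""
    values, back = m.values, m.backpointers
    h = values.shape[0]
    path = np.empty(h, dtype=np.int64)
    j = int(np.argmin(values[-1]))  # np.argmin returns the leftmost minimum
    path[-1] = j
    for i in range(h - 1, 0, -1):
        j = j + int(back[i, j])
        path[i - 1] = j
    return Seam(orientation=orientation, path=path)


def _delete_along_axis1(arr: np.ndarray, path: np.ndarray) -> np.ndarray:
    h, w = arr.shape[:2]
    keep = np.ones((h, w), dtype=bool)
    keep[np.arange(h), path] = False
    if arr.ndim == 3:
        return arr[keep].reshape(h, w - 1, arr.shape[2])
    return arr[keep].reshape(h, w - 1)


def remove_seam(image: np.ndarray, seam: Seam) -> np.ndarray:
    """Delete one pixel per row (vertical) or per column (horizontal);
    every non-seam pixel value is preserved bit-exactly."""
    arr = np.asarray(image)
    vertical = seam.orientation == "vertical"
    n_lines = arr.shape[0] if vertical else arr.shape[1]
    limit = arr.shape[1] if vertical else arr.shape[0]
    if seam.path.size != n_lines or seam.path.min() < 0 or seam.path.max() >= limit:
        raise InvalidInputError(
            f"seam of length {seam.path.size} does not fit image {arr.shape}"
        )
    if vertical:
        return _delete_along_axis1(arr, seam.path)
    out = _delete_along_axis1(arr.swapaxes(0, 1), seam.path)
    return out.swapaxes(0, 1)


def gradient_energy(image: np.ndarray) -> np.ndarray:
    """Baseline energy: L1 gradient magnitude of the luminance channel
    (ITU-R 601 luma of the RGB image, in [0, 255])."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        if arr.max() <= 1.0:
            arr = arr * 255.0
        arr = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return local_energy(arr)


def auto_target_size(
    eaws: Sequence[EllipseWindow],
    shape: tuple[int, int],
    margin: int = 20,
    policy: str = "union-span",
) -> tuple[int, int]:
    """Smallest target that keeps every EAW carvable without distortion.

    ``union-span`` (default) measures the bounding span of all EAW boxes
    per axis; ``projection`` counts only EAW-covered rows/columns.  The
    margin is added on both sides and the result clamped to the source.
    """
    if not eaws:
        raise NoAttentionWindowsError(
            "no EAWs found; specify an explicit target size"
        )
    h, w = shape
    if policy == "union-span":
        c_lo = min(e.cx - e.rx for e in eaws)
        c_hi = max(e.cx + e.rx for e in eaws)
        r_lo = min(e.cy - e.ry for e in eaws)
        r_hi = max(e.cy + e.ry for e in eaws)
        w_ext = int(np.ceil(c_hi)) - int(np.floor(c_lo))
        h_ext = int(np.ceil(r_hi)) - int(np.floor(r_lo))
    elif policy == "projection":
        cols = np.zeros(w, dtype=bool)
        rows = np.zeros(h, dtype=bool)
        for e in eaws:
            cols[max(int(np.floor(e.cx - e.rx)), 0):
                 min(int(np.ceil(e.cx + e.rx)), w)] = True
            rows[max(int(np.floor(e.cy - e.ry)), 0):
                 min(int(np.ceil(e.cy + e.ry)), h)] = True
        w_ext = int(cols.sum())
        h_ext = int(rows.sum())
    else:
        raise InvalidInputError(f"unknown auto-target policy {policy!r}")
    w_t = min(max(w_ext + 2 * margin, w_ext), w)
    h_t = min(max(h_ext + 2 * margin, h_ext), h)
    return h_t, w_t


def _carve_one(img, energy, orientation, use_numba):
    if orientation == "horizontal":
        e = np.ascontiguousarray(energy.T)
    else:
        e = energy
    seam = find_min_seam(build_cost_matrix(e, use_numba), orientation)
    img2 = remove_seam(img, seam)
    if orientation == "horizontal":
        energy2 = _delete_along_axis1(energy.T, seam.path).T
    else:
        energy2 = _delete_along_axis1(energy, seam.path)
    return img2, np.ascontiguousarray(energy2), seam


def resize(
    image: np.ndarray,
    target: tuple[int, int],
    energy: str = "ssm",
    energy_map: np.ndarray | None = None,
    recompute: Callable[[np.ndarray], np.ndarray] | None = None,
    recompute_every: int = 0,
    use_numba: bool | None = None,
) -> tuple[np.ndarray, list[Seam]]:
    """Carve ``image`` down to ``target`` = (H_t, W_t), alternating
    vertical and horizontal seams.

    ``energy='ssm'`` requires ``energy_map`` (the SSM); ``'gradient'``
    derives the baseline map from the image itself.  By default the
    stored energy raster just has each removed seam's entries deleted;
    pass ``recompute`` (image -> raster) with ``recompute_every=k`` to
    rebuild it every k removals.  Returns the carved image and the seam
    log (each seam in the frame it was removed from, top to bottom /
    left to right order of removal).
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    h_t, w_t = int(target[0]), int(target[1])
    if not (1 <= h_t <= h and 1 <= w_t <= w):
        raise InvalidInputError(
            f"target {(h_t, w_t)} not within source {(h, w)}; "
            "enlargement is unsupported"
        )
    if energy == "ssm":
        if energy_map is None:
            raise InvalidInputError("energy='ssm' requires an energy_map")
        emap = np.ascontiguousarray(energy_map, dtype=np.float64)
    elif energy == "gradient":
        emap = gradient_energy(img) if energy_map is None else \
            np.ascontiguousarray(energy_map, dtype=np.float64)
        if recompute is None and recompute_every:
            recompute = gradient_energy
    else:
        raise InvalidInputError(f"unknown energy mode {energy!r}")
    if emap.shape != img.shape[:2]:
        raise InvalidInputError(
            f"energy map {emap.shape} does not match image {img.shape[:2]}"
        )

    seams: list[Seam] = []
    removed = 0
    turn_vertical = True
    while img.shape[1] > w_t or img.shape[0] > h_t:
        need_v = img.shape[1] > w_t
        need_h = img.shape[0] > h_t
        orientation = "vertical" if (need_v and (turn_vertical or not need_h)) \
            else "horizontal"
        img, emap, seam = _carve_one(img, emap, orientation, use_numba)
        seams.append(seam)
        removed += 1
        turn_vertical = not turn_vertical
        if recompute is not None and recompute_every and \
                removed % recompute_every == 0:
            emap = np.ascontiguousarray(recompute(img), dtype=np.float64)
    return img, seams


def replay_seams(
    shape: tuple[int, int], seams: Sequence[Seam | dict]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replay a seam log to recover the pixel correspondence.

    Returns ``(survived, rows, cols)``: a boolean H x W mask of source
    pixels that survive all removals, and two H_t x W_t integer arrays
    giving, for each pixel of the carved result, its source row/column.
    """
    h, w = shape
    rows = np.broadcast_to(np.arange(h)[:, None], (h, w)).copy()
    cols = np.broadcast_to(np.arange(w)[None, :], (h, w)).copy()
    for s in seams:
        if isinstance(s, dict):
            s = Seam(orientation=s["orientation"],
                     path=np.asarray(s["path"], dtype=np.int64))
        rows = remove_seam(rows, s)
        cols = remove_seam(cols, s)
    survived = np.zeros((h, w), dtype=bool)
    survived[rows.ravel(), cols.ravel()] = True
    return survived, rows, cols
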