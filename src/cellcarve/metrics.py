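"""Quality metrics for carved images: MSE/PSNR and the per-nucleus
Ratio of Distortion (fraction of original nucleus pixels lost)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .carve import Seam, replay_seams
from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = ["QualityReport", "mse", "psnr", "rod", "evaluate"]


@dataclass
class QualityReport:
    """Aggregate and per-nucleus quality numbers."""

    mse: float
    psnr: float
    rod_per_nucleus: list[float] = field(default_factory=list)
    psnr_per_nucleus: list[float] = field(default_factory=list)

    @property
    def mean_rod(self) -> float:
        if not self.rod_per_nucleus:
            return math.nan
        return float(np.mean(self.rod_per_nucleus))

    def to_dict(self) -> dict:
        def enc(x):
            return "inf" if math.isinf(x) else x

        return {
            "mse": self.mse,
            "psnr_db": enc(self.psnr),
            "rod_per_nucleus": self.rod_per_nucleus,
            "mean_rod": self.mean_rod,
            "psnr_per_nucleus_db": [enc(p) for p in self.psnr_per_nucleus],
        }


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared intensity difference over all pixels and channels."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise InvalidInputError("cannot compute MSE of empty regions")
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 255.0) -> float:
    """10 log10(MAX^2 / MSE) in dB; +inf when the regions are identical."""
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value * max_value / err)


def rod(original: np.ndarray, resized: np.ndarray) -> float:
    """Ratio of Distortion between two nucleus masks in the same frame:
    |M \\ (M n S)| / |M|."""
    m = np.asarray(original, dtype=bool)
    s = np.asarray(resized, dtype=bool)
    if m.shape != s.shape:
        raise InvalidInputError(f"mask shapes differ: {m.shape} vs {s.shape}")
    card_m = int(m.sum())
    if card_m == 0:
        raise InvalidInputError("original nucleus mask is empty")
    return float((m & ~s).sum()) / card_m


def _bbox(mask: np.ndarray) -> tuple[slice, slice]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))


def evaluate(
    original: np.ndarray,
    resized: np.ndarray,
    masks_orig: Sequence[np.ndarray],
    masks_resized: Sequence[np.ndarray] | None = None,
    seam_log: Sequence[Seam | dict] | None = None,
) -> QualityReport:
    """Per-nucleus ROD and PSNR after carving.

    Masks are compared in the original frame.  When ``seam_log`` is
    given, the exact per-seam bookkeeping supplies the correspondence:
    resized masks (or, if omitted, the original masks themselves) are
    pulled back through it, and the PSNR compares each surviving pixel
    of a nucleus's bounding box with its carved counterpart.  Without a
    seam log the images must share a shape (identity correspondence).
    """
    original = np.asarray(original)
    resized = np.asarray(resized)
    shape = original.shape[:2]

    if seam_log is not None:
        survived, rows, cols = replay_seams(shape, seam_log)
        if rows.shape != resized.shape[:2]:
            raise InvalidInputError(
                f"seam log yields {rows.shape}, resized is {resized.shape[:2]}"
            )
        # position of each surviving source pixel in the carved frame
        pos_r = np.full(shape, -1, dtype=np.int64)
        pos_c = np.full(shape, -1, dtype=np.int64)
        grid_r = np.broadcast_to(
            np.arange(rows.shape[0])[:, None], rows.shape)
        grid_c = np.broadcast_to(
            np.arange(rows.shape[1])[None, :], rows.shape)
        pos_r[rows.ravel(), cols.ravel()] = grid_r.ravel()
        pos_c[rows.ravel(), cols.ravel()] = grid_c.ravel()
    elif original.shape[:2] == resized.shape[:2]:
        survived = np.ones(shape, dtype=bool)
        pos_r, pos_c = np.indices(shape)
        rows, cols = pos_r, pos_c
    else:
        raise InvalidInputError(
            "images of different shapes require a seam_log correspondence"
        )

    if masks_resized is None:
        # pull the original masks through the carving
        pulled = [np.asarray(m, dtype=bool) & survived for m in masks_orig]
    else:
        pulled = []
        for k, m in enumerate(masks_orig):
            if k >= len(masks_resized) or masks_resized[k] is None:
                logger.warning("nucleus %d has no resized mask; ROD = 1", k)
                pulled.append(np.zeros(shape, dtype=bool))
                continue
            s = np.asarray(masks_resized[k], dtype=bool)
            back = np.zeros(shape, dtype=bool)
            back[rows[s], cols[s]] = True
            pulled.append(back)

    rods: list[float] = []
    psnrs: list[float] = []
    sq_err_sum = 0.0
    n_vals = 0
    for m, s in zip(masks_orig, pulled):
        m = np.asarray(m, dtype=bool)
        rods.append(rod(m, s))
        box = _bbox(m)
        live = survived[box]
        a = original[box][live]
        b = resized[pos_r[box][live], pos_c[box][live]]
        if a.size == 0:
            psnrs.append(0.0)
            continue
        psnrs.append(psnr(a, b))
        sq_err_sum += float(
            np.sum((a.astype(np.float64) - b.astype(np.float64)) ** 2))
        n_vals += a.size

    total_mse = sq_err_sum / n_vals if n_vals else 0.0
    total_psnr = math.inf if total_mse == 0 else 10.0 * math.log10(
        255.0 ** 2 / total_mse)
    return QualityReport(
        mse=total_mse,
        psnr=total_psnr,
        rod_per_nucleus=rods,
        psnr_per_nucleus=psnrs,
    )
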