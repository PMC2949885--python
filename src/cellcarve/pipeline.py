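"""End-to-end orchestration: saliency -> attention -> SSM -> carving.

The pipeline is fully deterministic; no stage consumes randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import attention, carve, saliency, ssm
from .config import PipelineConfig
from .exceptions import CellCarveError, InvalidConfigError

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    resized: np.ndarray
    target: tuple[int, int]
    seam_log: list[carve.Seam] = field(default_factory=list)
    saliency_map: np.ndarray | None = None
    ssm_map: np.ndarray | None = None
    eaws: list[attention.EllipseWindow] = field(default_factory=list)
    mask: np.ndarray | None = None


def _stage(name: str):
    """Re-raise stage failures with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CellCarveError):
                exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",)
            return False
    return _Ctx()


def run_pipeline(
    image: np.ndarray, cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Resize ``image`` per the configuration.

    With ``energy='ssm'`` the full chain runs and the target defaults to
    the automatic EAW-derived size.  With ``energy='gradient'`` the
    saliency stages are bypassed and an explicit ``cfg.target`` is
    required.
    """
    cfg = cfg or PipelineConfig()
    img = np.asarray(image)
    shape = img.shape[:2]
    eff = cfg.scaled_to(shape)

    if eff.energy == "gradient":
        if eff.target is None:
            raise InvalidConfigError(
                "energy='gradient' bypasses EAW detection; an explicit "
                "target size is required"
            )
        with _stage("carve"):
            resized, seams = carve.resize(img, eff.target, energy="gradient",
                                          recompute_every=eff.recompute_every)
        return PipelineResult(resized=resized, target=tuple(eff.target),
                              seam_log=seams)

    with _stage("saliency"):
        cm = saliency.compute_saliency(img, eff.saliency)
    with _stage("attention"):
        eaws, mask = attention.detect_eaws(
            cm, closing_radius=eff.closing_radius,
            min_fraction=eff.min_region_fraction)
        eaw_s = attention.eaw_strength(eaws, shape)
    with _stage("ssm"):
        ssm_map = ssm.build_ssm(cm, eaw_s, eff.smoothing)
    with _stage("carve"):
        target = eff.target or carve.auto_target_size(
            eaws, shape, margin=eff.margin, policy=eff.target_policy)
        recompute = None
        if eff.recompute_every:
            def recompute(im):  # full SSM rebuild on the carved image
                sub = eff.scaled_to(im.shape[:2])
                cm2 = saliency.compute_saliency(im, sub.saliency)
                eaws2, _ = attention.detect_eaws(
                    cm2, closing_radius=sub.closing_radius,
                    min_fraction=sub.min_region_fraction)
                eaw2 = attention.eaw_strength(eaws2, im.shape[:2])
                return ssm.build_ssm(cm2, eaw2, sub.smoothing)
        resized, seams = carve.resize(
            img, target, energy="ssm", energy_map=ssm_map,
            recompute=recompute, recompute_every=eff.recompute_every)

    logger.info("carved %s -> %s with %d seams", shape,
                resized.shape[:2], len(seams))
    return PipelineResult(
        resized=resized, target=tuple(target), seam_log=seams,
        saliency_map=cm, ssm_map=ssm_map, eaws=eaws, mask=mask,
    )
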