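"""Perfusion-image quality metrics on label/control difference volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, StructuralError
from .segmentation import TissueMasks

__all__ = ["PerfusionReport", "evaluate_perfusion"]


@dataclass(frozen=True)
class PerfusionReport:
    """Summary of a mean difference volume.

    ``sbr`` is ``mean_gm_diff / background_sd``; when the background is
    exactly noiseless (``background_sd == 0``) it is reported as signed
    infinity and flagged.
    """

    mean_gm_diff: float
    background_sd: float
    sbr: float
    rcbf_gm: float
    background_noiseless: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_gm_diff": self.mean_gm_diff,
            "background_sd": self.background_sd,
            "sbr": self.sbr,
            "rcbf_gm": self.rcbf_gm,
            "background_noiseless": self.background_noiseless,
        }


def evaluate_perfusion(
    diff_volume: np.ndarray,
    masks: TissueMasks,
    background: np.ndarray,
) -> PerfusionReport:
    """Quality metrics of a mean control-minus-label difference volume.

    ``rcbf_gm`` is the mean difference signal over the GM mask, in the
    arbitrary units of the input — a relative perfusion measure, not an
    absolute CBF.  The background mask must be disjoint from all tissue
    masks (default choice upstream: the air region of the phantom).
    """
    diff = np.asarray(diff_volume, dtype=float)
    background = np.asarray(background, dtype=bool)
    if diff.shape != masks.shape or background.shape != diff.shape:
        raise StructuralError("diff volume, masks and background must share one shape")
    if np.any(background & (masks.gm | masks.wm | masks.csf)):
        raise StructuralError("background mask overlaps a tissue mask")
    if not masks.gm.any():
        raise DegenerateDataError("empty GM mask")
    if background.sum() < 2:
        raise DegenerateDataError("background mask needs >= 2 voxels")

    mean_gm = float(diff[masks.gm].mean())
    bg_sd = float(diff[background].std(ddof=1))
    if bg_sd > 0:
        sbr = mean_gm / bg_sd
        noiseless = False
    else:
        sbr = float(np.copysign(np.inf, mean_gm)) if mean_gm != 0 else float("inf")
        noiseless = True
    return PerfusionReport(
        mean_gm_diff=mean_gm,
        background_sd=bg_sd,
        sbr=sbr,
        rcbf_gm=mean_gm,
        background_noiseless=noiseless,
    )
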