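"""Intensity-driven GM/WM/CSF classification on a T1 map.

Stand-in for atlas-based segmentation: classes are separable on T1 alone
(WM < GM << CSF), so a 1-D three-component Gaussian mixture — or fixed T1
windows — assigns each valid voxel a tissue.  Also provides the masked
mean-T1 reduction that feeds the timing optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .exceptions import DegenerateDataError, ParameterError, StructuralError
from .vfa_t1 import T1Map

__all__ = ["TissueMasks", "segment_t1", "mean_tissue_t1", "DEFAULT_WINDOWS_MS"]

#: Default fixed T1 windows in ms, spanning the cohort range per tissue.
DEFAULT_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "wm": (500.0, 1100.0),
    "gm": (1100.0, 2000.0),
    "csf": (3000.0, float("inf")),
}


@dataclass
class TissueMasks:
    """Pairwise-disjoint boolean masks for the three tissue classes."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise StructuralError("masks must share one shape")
        if (
            np.any(self.gm & self.wm)
            or np.any(self.gm & self.csf)
            or np.any(self.wm & self.csf)
        ):
            raise StructuralError("tissue masks must be pairwise disjoint")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape

    def __getitem__(self, tissue: str) -> np.ndarray:
        return {"gm": self.gm, "wm": self.wm, "csf": self.csf}[tissue]


def segment_t1(
    t1_map: T1Map,
    method: str = "gmm3",
    windows: Mapping[str, tuple[float, float]] | Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    t1_range: tuple[float, float] = (100.0, 6000.0),
    m0_floor: float = 0.2,
) -> TissueMasks:
    """Classify valid voxels of a T1 map into WM/GM/CSF.

    ``gmm3`` fits a three-component 1-D Gaussian mixture to the valid T1
    values (deterministic quantile initialization) and maps components to
    tissues by ascending mean -> (WM, GM, CSF).  ``fixed-windows`` assigns
    by the supplied ``(lo, hi)`` ranges; voxels matching no window stay
    unassigned.

    ``t1_range`` bounds the physically plausible tissue T1s: values outside
    it (typically noise-only voxels whose fitted slope landed near 1) are
    left unassigned and never enter the mixture fit.  Voxels whose fitted
    M0 falls below ``m0_floor`` times the median valid M0 are likewise
    treated as non-brain (air fits a near-zero M0).
    """
    valid = t1_map.valid & (t1_map.t1 >= t1_range[0]) & (t1_map.t1 <= t1_range[1])
    if m0_floor > 0 and valid.any():
        m0_med = float(np.nanmedian(t1_map.m0[valid]))
        if m0_med > 0:
            valid &= t1_map.m0 >= m0_floor * m0_med
    vals = t1_map.t1[valid]
    assign = np.zeros(t1_map.shape, dtype=np.int8)  # 0 unassigned, 1 wm, 2 gm, 3 csf

    if method == "gmm3":
        if np.unique(vals).size < 3:
            raise DegenerateDataError(
                "gmm3 needs at least 3 distinct valid T1 values"
            )
        x = vals.reshape(-1, 1)
        # k-means initialization (seeded): quantile seeding collapses when one
        # class holds the bulk of the voxels
        gmm = GaussianMixture(
            n_components=3,
            n_init=1,
            init_params="kmeans",
            random_state=seed,
            covariance_type="full",
        )
        comp = gmm.fit_predict(x)
        order = np.argsort(gmm.means_.ravel())  # ascending T1: wm, gm, csf
        remap = np.empty(3, dtype=np.int8)
        remap[order] = [1, 2, 3]
        assign[valid] = remap[comp]
    elif method == "fixed-windows":
        if windows is None:
            windows = DEFAULT_WINDOWS_MS
        if not isinstance(windows, Mapping):
            wm_w, gm_w, csf_w = windows
            windows = {"wm": wm_w, "gm": gm_w, "csf": csf_w}
        codes = {"wm": 1, "gm": 2, "csf": 3}
        sub = np.zeros(vals.shape, dtype=np.int8)
        for tissue, (lo, hi) in windows.items():
            if lo >= hi:
                raise ParameterError(f"window for {tissue} must have lo < hi")
            sub[(vals >= lo) & (vals < hi)] = codes[tissue]
        assign[valid] = sub
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")

    return TissueMasks(gm=assign == 2, wm=assign == 1, csf=assign == 3)


def mean_tissue_t1(t1_map: T1Map, mask: np.ndarray) -> float:
    """Arithmetic mean of T1 over ``mask AND valid``, in ms.

    Invalid voxels never contribute; an empty intersection is an error
    rather than a NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t1_map.shape:
        raise StructuralError("mask shape must match the T1 map")
    sel = mask & t1_map.valid
    if not sel.any():
        raise DegenerateDataError("mask does not intersect the valid region")
    return float(t1_map.t1[sel].mean())
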