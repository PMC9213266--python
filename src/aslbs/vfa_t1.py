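"""Two-point variable-flip-angle T1/M0 estimation.

The linearized route rewrites the spoiled-gradient-echo equation as a line,
``S/sin(fa) = E1 * S/tan(fa) + M0*(1 - E1)``, so two flip angles give the
slope ``E1`` directly and ``T1 = -TR / ln(E1)``.  A direct nonlinear
least-squares fit of the same signal equation is provided as a cross-check;
on noiseless data the two agree to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ParameterError, StructuralError

__all__ = ["T1Map", "fit_t1_vfa", "fit_t1_vfa_nls"]


@dataclass
class T1Map:
    """Voxelwise T1/M0 estimate with a validity mask.

    ``t1`` and ``m0`` hold NaN where ``valid`` is false; valid voxels carry
    strictly positive T1.
    """

    t1: np.ndarray
    m0: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (self.t1.shape == self.m0.shape == self.valid.shape):
            raise StructuralError("t1, m0 and valid must share one shape")
        if np.any(self.t1[self.valid] <= 0):
            raise StructuralError("valid voxels must have t1 > 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1.shape


def _check_inputs(signal_low, signal_high, fa_low, fa_high, tr):
    s_low = np.asarray(signal_low, dtype=float)
    s_high = np.asarray(signal_high, dtype=float)
    if s_low.shape != s_high.shape:
        raise StructuralError(
            f"signal shapes differ: {s_low.shape} vs {s_high.shape}"
        )
    if fa_low == fa_high:
        raise ParameterError("flip angles must differ")
    for fa in (fa_low, fa_high):
        if not (0.0 < fa < 90.0):
            raise ParameterError(f"flip angle {fa} outside (0, 90)")
    if tr <= 0:
        raise ParameterError("tr must be > 0")
    return s_low, s_high


def fit_t1_vfa(signal_low, signal_high, fa_low: float, fa_high: float, tr: float) -> T1Map:
    """Linearized two-point VFA fit.

    Parameters
    ----------
    signal_low, signal_high
        Magnitude volumes acquired at ``fa_low`` and ``fa_high`` degrees.
        The fit is symmetric in the two inputs: either one may have been
        the label or the control condition.
    tr
        Excitation repetition time in ms.

    Returns
    -------
    T1Map
        Voxels with non-positive/non-finite signals or a slope outside
        ``(0, 1)`` are marked invalid (no clipping to a T1 ceiling).
    """
    s_low, s_high = _check_inputs(signal_low, signal_high, fa_low, fa_high, tr)
    a_low, a_high = np.deg2rad(fa_low), np.deg2rad(fa_high)

    with np.errstate(divide="ignore", invalid="ignore"):
        y_low = s_low / np.sin(a_low)
        y_high = s_high / np.sin(a_high)
        x_low = s_low / np.tan(a_low)
        x_high = s_high / np.tan(a_high)
        denom = x_high - x_low
        slope = (y_high - y_low) / denom
        intercept = y_low - slope * x_low

    finite = np.isfinite(s_low) & np.isfinite(s_high)
    valid = finite & (s_low > 0) & (s_high > 0) & (denom != 0)
    valid &= np.isfinite(slope) & (slope > 0) & (slope < 1)

    t1 = np.full(s_low.shape, np.nan)
    m0 = np.full(s_low.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1[valid] = -tr / np.log(slope[valid])
        m0[valid] = intercept[valid] / (1.0 - slope[valid])
    valid &= np.isfinite(t1) & (t1 > 0)
    t1[~valid] = np.nan
    m0[~valid] = np.nan
    return T1Map(t1=t1, m0=m0, valid=valid)


def fit_t1_vfa_nls(
    signal_low, signal_high, fa_low: float, fa_high: float, tr: float
) -> T1Map:
    """Voxelwise nonlinear least-squares fit of the SPGR signal equation.

    Cross-check estimator for :func:`fit_t1_vfa`; slower (per-voxel
    optimization), intended for validation and small volumes.  Voxels where
    the solver fails to converge are marked invalid.
    """
    s_low, s_high = _check_inputs(signal_low, signal_high, fa_low, fa_high, tr)
    lin = fit_t1_vfa(s_low, s_high, fa_low, fa_high, tr)

    angles = np.deg2rad([fa_low, fa_high])
    sin_a, cos_a = np.sin(angles), np.cos(angles)

    def model(params):
        t1, m0 = params
        e1 = np.exp(-tr / t1)
        return m0 * sin_a * (1.0 - e1) / (1.0 - e1 * cos_a)

    t1 = np.full(s_low.shape, np.nan)
    m0 = np.full(s_low.shape, np.nan)
    valid = np.zeros(s_low.shape, dtype=bool)

    candidates = np.argwhere(np.isfinite(s_low) & np.isfinite(s_high) & (s_low > 0) & (s_high > 0))
    for idx in map(tuple, candidates):
        data = np.array([s_low[idx], s_high[idx]])
        if lin.valid[idx]:
            x0 = np.array([lin.t1[idx], lin.m0[idx]])
        else:
            x0 = np.array([1000.0, float(data.max())])
        try:
            sol = least_squares(
                lambda p: model(p) - data,
                x0,
                bounds=([1e-3, 1e-12], [1e7, np.inf]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        # a fit that cannot explain the data (residual comparable to the
        # signal) is no estimate at all
        if np.linalg.norm(sol.fun) > 1e-6 * max(np.linalg.norm(data), 1e-30):
            continue
        t1[idx], m0[idx] = sol.x
        valid[idx] = True
    return T1Map(t1=t1, m0=m0, valid=valid)
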