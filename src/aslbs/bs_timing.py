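"""Background-suppression pulse timing: Bloch simulation and optimization.

Longitudinal magnetization under a presaturation pulse followed by a train
of nonselective inversion pulses has a closed-form piecewise solution:
between events ``Mz(t) = M0 + (Mz+ - M0) * exp(-dt/T1)``; an inversion
pulse with efficiency ``eta`` maps ``Mz -> (1 - 2*eta) * Mz``.  The
optimizer places the pulse times so that the residual magnetization of a
set of target T1 species is as close to zero as possible at readout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .exceptions import ParameterError, ResourceError, StructuralError

__all__ = [
    "BSSchedule",
    "SuppressionResult",
    "mz_at_readout",
    "evaluate_schedule",
    "optimize_schedule",
    "compare_schedules",
]

#: Literature tissue T1 values (ms, 3 T) used for the routine fixed schedule.
LITERATURE_T1_MS: dict[str, float] = {"gm": 1300.0, "wm": 850.0}


@dataclass(frozen=True)
class BSSchedule:
    """An ordered train of inversion pulses within the labeling+PLD window.

    Parameters
    ----------
    pulse_times
        Strictly increasing pulse times in ms, measured from the start of
        labeling; each must lie in ``[0, readout_time]``.
    inversion_efficiency
        Fraction ``eta`` in ``(0.5, 1]``; a pulse maps ``Mz`` to
        ``(1 - 2*eta) * Mz``.
    presaturation
        If true the longitudinal magnetization starts at 0 (saturated),
        otherwise at equilibrium ``M0``.
    readout_time
        Time of image acquisition in ms (labeling duration + post-labeling
        delay).
    """

    pulse_times: tuple[float, ...] = ()
    inversion_efficiency: float = 1.0
    presaturation: bool = True
    readout_time: float = 3700.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.pulse_times)
        object.__setattr__(self, "pulse_times", times)
        if not self.readout_time > 0:
            raise StructuralError("readout_time must be > 0")
        if not (0.5 < self.inversion_efficiency <= 1.0):
            raise ParameterError(
                "inversion_efficiency must lie in (0.5, 1], got "
                f"{self.inversion_efficiency}"
            )
        for t in times:
            if not (0.0 <= t <= self.readout_time):
                raise StructuralError(
                    f"pulse time {t} outside [0, {self.readout_time}]"
                )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise StructuralError(f"pulse times must be strictly increasing: {times}")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)

    def to_dict(self) -> dict:
        return {
            "pulse_times": list(self.pulse_times),
            "inversion_efficiency": self.inversion_efficiency,
            "presaturation": self.presaturation,
            "readout_time": self.readout_time,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BSSchedule":
        return cls(
            pulse_times=tuple(d["pulse_times"]),
            inversion_efficiency=float(d["inversion_efficiency"]),
            presaturation=bool(d["presaturation"]),
            readout_time=float(d["readout_time"]),
        )


@dataclass(frozen=True)
class SuppressionResult:
    """Residual magnetization per target T1 and the scalar objective."""

    residual_mz: dict[float, float] = field(default_factory=dict)
    objective: float = 0.0

    def to_dict(self) -> dict:
        return {
            "residual_mz": {str(k): v for k, v in self.residual_mz.items()},
            "objective": self.objective,
        }


def _mz_closed_form(
    times: np.ndarray,
    t1: np.ndarray | float,
    readout_time: float,
    eta: float,
    presaturation: bool,
) -> np.ndarray:
    """Propagate Mz/M0 through a pulse train, vectorized over leading axes.

    ``times`` has shape ``(..., n_pulses)`` with rows sorted ascending;
    ``t1`` must broadcast against ``times[..., 0]``.
    """
    t1 = np.asarray(t1, dtype=float)
    flip = 1.0 - 2.0 * eta
    if times.ndim == 1:
        lead = t1.shape
    else:
        lead = np.broadcast_shapes(times.shape[:-1], t1.shape)
    m = np.zeros(lead) if presaturation else np.ones(lead)
    prev: np.ndarray | float = 0.0
    for j in range(times.shape[-1]):
        tj = times[..., j]
        m = 1.0 + (m - 1.0) * np.exp(-(tj - prev) / t1)
        m = flip * m
        prev = tj
    m = 1.0 + (m - 1.0) * np.exp(-(readout_time - prev) / t1)
    return m


def mz_at_readout(schedule: BSSchedule, t1):
    """Normalized longitudinal magnetization ``Mz/M0`` at readout.

    Parameters
    ----------
    schedule
        Pulse train and timing window.
    t1
        Longitudinal relaxation time in ms; scalar or array (vectorized).

    Returns
    -------
    float or ndarray
        Signed fraction of ``M0``; always within ``[-1, 1]``.
    """
    t1_arr = np.asarray(t1, dtype=float)
    if np.any(t1_arr <= 0):
        raise ParameterError("t1 must be > 0")
    times = np.asarray(schedule.pulse_times, dtype=float)
    out = _mz_closed_form(
        times,
        t1_arr,
        schedule.readout_time,
        schedule.inversion_efficiency,
        schedule.presaturation,
    )
    if np.isscalar(t1) or t1_arr.ndim == 0:
        return float(out)
    return out


def evaluate_schedule(
    schedule: BSSchedule,
    target_t1s: Sequence[float],
    weights: Sequence[float] | None = None,
    objective: str = "ssq",
) -> SuppressionResult:
    """Residuals of a schedule on a set of target T1s plus scalar objective."""
    t1s = [float(t) for t in target_t1s]
    if not t1s:
        raise ParameterError("target_t1s must be non-empty")
    w = _check_weights(weights, len(t1s))
    res = {t1: float(mz_at_readout(schedule, t1)) for t1 in t1s}
    vals = np.array([res[t1] for t1 in t1s])
    if objective == "ssq":
        obj = float(np.sum(w * vals**2))
    elif objective == "maxabs":
        obj = float(np.max(np.abs(vals)))
    else:
        raise ParameterError(f"unknown objective {objective!r}")
    return SuppressionResult(residual_mz=res, objective=obj)


def _check_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise StructuralError("weights must match target_t1s in length")
    if np.any(w < 0):
        raise ParameterError("weights must be non-negative")
    return w


def _grid_objective(
    cand: np.ndarray,
    t1s: Sequence[float],
    w: np.ndarray,
    readout_time: float,
    eta: float,
    presat: bool,
    objective: str,
) -> np.ndarray:
    """Objective of every candidate pulse tuple, shape (n_candidates,)."""
    parts = []
    for t1 in t1s:
        parts.append(_mz_closed_form(cand, float(t1), readout_time, eta, presat))
    mz = np.stack(parts, axis=0)  # (n_t1, n_candidates)
    if objective == "ssq":
        return np.einsum("i,i...->...", w, mz**2)
    return np.max(np.abs(mz), axis=0)


def optimize_schedule(
    n_pulses: int,
    target_t1s: Sequence[float],
    weights: Sequence[float] | None = None,
    timeline: tuple[float, float] = (2000.0, 1700.0),
    inversion_efficiency: float = 1.0,
    grid_ms: float = 10.0,
    refine: bool = True,
    presaturation: bool = True,
    objective: str = "ssq",
    max_candidates: int = 5_000_000,
) -> tuple[BSSchedule, SuppressionResult]:
    """Optimize inversion-pulse times to null the target T1s at readout.

    Minimizes ``sum_i w_i * (Mz_i(readout)/M0)**2`` (or the max-abs
    residual) over ordered pulse-time tuples inside
    ``[0, labeling_duration + pld]`` by exhaustive coarse grid search
    followed by bounded local refinement.

    Returns
    -------
    (BSSchedule, SuppressionResult)
        Best schedule found and its residuals.  Deterministic: grid ties
        resolve to the lexicographically smallest tuple.

    Raises
    ------
    ResourceError
        If the coarse grid would enumerate more than ``max_candidates``
        tuples.  Never silently truncates.
    """
    if int(n_pulses) != n_pulses or n_pulses < 0:
        raise ParameterError("n_pulses must be a non-negative integer")
    n_pulses = int(n_pulses)
    t1s = [float(t) for t in target_t1s]
    if not t1s or any(t <= 0 for t in t1s):
        raise ParameterError("target_t1s must be non-empty and all > 0")
    if grid_ms < 1.0:
        raise ParameterError("grid_ms must be >= 1 ms")
    labeling_duration, pld = timeline
    if labeling_duration <= 0 or pld < 0:
        raise ParameterError("timeline must have labeling > 0 and pld >= 0")
    readout_time = float(labeling_duration + pld)
    w = _check_weights(weights, len(t1s))

    if n_pulses == 0:
        sched = BSSchedule(
            pulse_times=(),
            inversion_efficiency=inversion_efficiency,
            presaturation=presaturation,
            readout_time=readout_time,
        )
        return sched, evaluate_schedule(sched, t1s, w, objective)

    points = np.arange(0.0, readout_time + grid_ms / 2.0, grid_ms)
    points = points[points <= readout_time]
    n_cand = math.comb(len(points), n_pulses)
    if n_cand > max_candidates:
        raise ResourceError(
            f"grid search would enumerate {n_cand} candidates "
            f"(> cap {max_candidates}); coarsen grid_ms or reduce n_pulses"
        )
    cand = np.array(list(itertools.combinations(points, n_pulses)))
    obj = _grid_objective(
        cand, t1s, w, readout_time, inversion_efficiency, presaturation, objective
    )
    best_idx = int(np.argmin(obj))  # first occurrence = lexicographically smallest
    best_times = cand[best_idx]
    best_obj = float(obj[best_idx])

    if refine:
        refined = _refine(
            best_times,
            t1s,
            w,
            readout_time,
            inversion_efficiency,
            presaturation,
            objective,
        )
        if refined is not None:
            r_times, r_obj = refined
            if r_obj <= best_obj:
                best_times, best_obj = r_times, r_obj

    try:
        sched = BSSchedule(
            pulse_times=tuple(best_times),
            inversion_efficiency=inversion_efficiency,
            presaturation=presaturation,
            readout_time=readout_time,
        )
    except StructuralError:
        # refinement merged two pulses; fall back to the feasible grid optimum
        sched = BSSchedule(
            pulse_times=tuple(cand[best_idx]),
            inversion_efficiency=inversion_efficiency,
            presaturation=presaturation,
            readout_time=readout_time,
        )
    return sched, evaluate_schedule(sched, t1s, w, objective)


def _refine(x0, t1s, w, readout_time, eta, presat, objective):
    """Local refinement from the coarse optimum; returns (times, obj) or None."""
    sw = np.sqrt(w)

    if objective == "ssq":

        def residuals(x):
            times = np.sort(x)
            return sw * np.array(
                [
                    _mz_closed_form(times, t1, readout_time, eta, presat)
                    for t1 in t1s
                ]
            )

        sol = least_squares(
            residuals,
            np.asarray(x0, dtype=float),
            bounds=(0.0, readout_time),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        times = np.sort(sol.x)
        obj = float(np.sum(residuals(sol.x) ** 2))
        return times, obj

    def fun(x):
        times = np.sort(x)
        vals = [
            abs(float(_mz_closed_form(times, t1, readout_time, eta, presat)))
            for t1 in t1s
        ]
        return max(vals)

    sol = minimize(fun, np.asarray(x0, dtype=float), method="Nelder-Mead")
    times = np.clip(np.sort(sol.x), 0.0, readout_time)
    return times, fun(times)


def compare_schedules(
    fixed: BSSchedule,
    adapted: BSSchedule,
    subject_t1s: Sequence[float],
    weights: Sequence[float] | None = None,
) -> dict:
    """Residuals of a fixed vs an individually adapted schedule on a subject.

    Both schedules must share the same timing window.  The report carries
    per-T1 residuals, the two objectives, their ratio, and a flag stating
    whether the adapted schedule dominates on the subject's own T1s.
    """
    if fixed.readout_time != adapted.readout_time:
        raise StructuralError("schedules must share the same readout_time")
    res_fixed = evaluate_schedule(fixed, subject_t1s, weights)
    res_adapted = evaluate_schedule(adapted, subject_t1s, weights)
    if res_fixed.objective > 0:
        ratio = res_adapted.objective / res_fixed.objective
    else:
        ratio = 1.0 if res_adapted.objective == 0 else float("inf")
    return {
        "subject_t1s": [float(t) for t in subject_t1s],
        "residuals_fixed": res_fixed.residual_mz,
        "residuals_adapted": res_adapted.residual_mz,
        "objective_fixed": res_fixed.objective,
        "objective_adapted": res_adapted.objective,
        "objective_ratio": ratio,
        "adapted_dominates": res_adapted.objective <= res_fixed.objective,
    }
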