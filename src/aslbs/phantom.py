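"""Synthetic tissue phantoms and forward MR signal simulation.

Everything downstream of the scanner is testable against these phantoms:
a labeled GM/WM/CSF volume with assigned T1/M0, spoiled-gradient-echo
signals at two flip angles, and label/control ASL volumes under a given
background-suppression schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bs_timing import BSSchedule, mz_at_readout
from .exceptions import ParameterError, StructuralError

__all__ = [
    "BACKGROUND",
    "GM",
    "WM",
    "CSF",
    "AcquisitionConfig",
    "TissuePhantom",
    "make_phantom",
    "simulate_spgr",
    "simulate_asl_pair",
]

BACKGROUND, GM, WM, CSF = 0, 1, 2, 3
TISSUES = {"gm": GM, "wm": WM, "csf": CSF}

#: Default tissue parameters (cohort means for T1; M0/perfusion arbitrary units).
DEFAULT_T1_MS = {"gm": 1442.8, "wm": 900.2, "csf": 4042.9}
DEFAULT_M0 = {"gm": 1.0, "wm": 0.9, "csf": 1.1}
DEFAULT_PERFUSION = {"gm": 0.01, "wm": 0.003, "csf": 0.0}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters; defaults mirror the protocol in use.

    ``tr`` is treated as the effective excitation repetition time of the
    two-flip-angle signal equation (the sequence TR is the only value the
    protocol exposes).
    """

    tr: float = 4000.0
    te: float = 12.06
    labeling_duration: float = 2000.0
    post_labeling_delay: float = 1700.0
    fa_low: float = 9.0
    fa_high: float = 20.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ParameterError("tr must be > 0")
        if self.labeling_duration <= 0:
            raise ParameterError("labeling_duration must be > 0")
        if self.post_labeling_delay < 0:
            raise ParameterError("post_labeling_delay must be >= 0")
        if not (0.0 < self.fa_low < self.fa_high < 90.0):
            raise ParameterError(
                "flip angles must satisfy 0 < fa_low < fa_high < 90, got "
                f"{self.fa_low}, {self.fa_high}"
            )
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    @property
    def readout_time(self) -> float:
        """Time of readout relative to start of labeling (ms)."""
        return self.labeling_duration + self.post_labeling_delay

    def to_dict(self) -> dict:
        return {
            "tr": self.tr,
            "te": self.te,
            "labeling_duration": self.labeling_duration,
            "post_labeling_delay": self.post_labeling_delay,
            "fa_low": self.fa_low,
            "fa_high": self.fa_high,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }


@dataclass
class TissuePhantom:
    """Labeled ground-truth volume with per-voxel T1, M0 and perfusion."""

    labels: np.ndarray
    t1: np.ndarray
    m0: np.ndarray
    perfusion: np.ndarray
    voxel_size: tuple[float, float, float] = (3.6, 3.6, 4.0)

    def __post_init__(self) -> None:
        shapes = {self.labels.shape, self.t1.shape, self.m0.shape, self.perfusion.shape}
        if len(shapes) != 1:
            raise StructuralError("all phantom volumes must share one shape")
        fg = self.labels > 0
        if np.any(self.t1[fg] <= 0) or np.any(self.m0[fg] <= 0):
            raise ParameterError("t1 and m0 must be > 0 on foreground voxels")
        if np.any(self.t1[~fg] != 0) or np.any(self.m0[~fg] != 0):
            raise StructuralError("t1 and m0 must be 0 on background voxels")
        no_perf = (self.labels == BACKGROUND) | (self.labels == CSF)
        if np.any(self.perfusion[no_perf] != 0):
            raise StructuralError("perfusion must be 0 in background and CSF")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


def _nested_sphere_labels(shape: tuple[int, int, int]) -> np.ndarray:
    # concentric shells: CSF core, WM interior, GM outer shell
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    rho = np.zeros(shape)
    for g, n in zip(grids, shape):
        c = (n - 1) / 2.0
        rho += ((g - c) / c) ** 2
    rho = np.sqrt(rho)
    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[rho <= 0.92] = GM
    labels[rho <= 0.62] = WM
    labels[rho <= 0.28] = CSF
    return labels


def _block_labels(shape: tuple[int, int, int]) -> np.ndarray:
    # three slabs along axis 0 inside a one-voxel background border
    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    thirds = np.array_split(np.arange(1, shape[0] - 1), 3)
    for sl, tissue in zip(thirds, (GM, WM, CSF)):
        labels[sl[0] : sl[-1] + 1, 1:-1, 1:-1] = tissue
    return labels


def make_phantom(
    shape: tuple[int, int, int] = (32, 32, 16),
    t1_by_tissue: Mapping[str, float] | None = None,
    m0_by_tissue: Mapping[str, float] | None = None,
    geometry: str = "nested-spheres",
    seed: int = 0,
    perfusion_by_tissue: Mapping[str, float] | None = None,
    voxel_size: tuple[float, float, float] = (3.6, 3.6, 4.0),
) -> TissuePhantom:
    """Build a deterministic three-tissue phantom.

    Parameters
    ----------
    shape
        Volume shape; every dimension must be >= 8.
    t1_by_tissue, m0_by_tissue, perfusion_by_tissue
        Per-tissue values keyed by ``gm``/``wm``/``csf``; defaults are the
        packaged cohort means (T1) and unit-scale M0.
    geometry
        ``nested-spheres`` (CSF core, WM interior, GM shell) or ``blocks``.
    seed
        Kept for interface stability; the construction is deterministic.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or any(n < 8 for n in shape):
        raise ParameterError(f"shape must be a 3-tuple with dims >= 8, got {shape}")
    t1 = dict(DEFAULT_T1_MS, **(t1_by_tissue or {}))
    m0 = dict(DEFAULT_M0, **(m0_by_tissue or {}))
    perf = dict(DEFAULT_PERFUSION, **(perfusion_by_tissue or {}))
    for name, val in t1.items():
        if val <= 0:
            raise ParameterError(f"T1 for {name} must be > 0, got {val}")
    for name, val in m0.items():
        if val <= 0:
            raise ParameterError(f"M0 for {name} must be > 0, got {val}")
    if perf.get("csf", 0.0) != 0.0:
        raise ParameterError("CSF perfusion must be 0")

    if geometry == "nested-spheres":
        labels = _nested_sphere_labels(shape)
    elif geometry == "blocks":
        labels = _block_labels(shape)
    else:
        raise ParameterError(f"unknown geometry {geometry!r}")

    t1_vol = np.zeros(shape)
    m0_vol = np.zeros(shape)
    perf_vol = np.zeros(shape)
    for name, code in TISSUES.items():
        mask = labels == code
        t1_vol[mask] = t1[name]
        m0_vol[mask] = m0[name]
        if code != CSF:
            perf_vol[mask] = perf.get(name, 0.0)
    return TissuePhantom(
        labels=labels,
        t1=t1_vol,
        m0=m0_vol,
        perfusion=perf_vol,
        voxel_size=voxel_size,
    )


def spgr_signal(m0, t1, fa_deg: float, tr: float):
    """Spoiled-gradient-echo steady-state signal (elementwise).

    ``S = M0 * sin(fa) * (1 - E1) / (1 - E1 * cos(fa))`` with
    ``E1 = exp(-TR/T1)``.
    """
    fa = np.deg2rad(fa_deg)
    t1 = np.asarray(t1, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    e1 = np.zeros_like(t1)
    pos = t1 > 0
    e1[pos] = np.exp(-tr / t1[pos])
    return m0 * np.sin(fa) * (1.0 - e1) / (1.0 - e1 * np.cos(fa))


def simulate_spgr(
    phantom: TissuePhantom,
    config: AcquisitionConfig,
    fa: float,
    noise_sigma: float | None = None,
    seed=None,
) -> np.ndarray:
    """Simulate a magnitude spoiled-gradient-echo volume at flip angle ``fa``.

    Noise (if ``noise_sigma > 0``, expressed as a fraction of the mean
    foreground signal) is zero-mean Gaussian added everywhere, after which
    the magnitude is taken.  Deterministic for a fixed seed; by default the
    seed is derived from ``config.seed`` and the flip angle so the two
    acquisitions have independent noise.
    """
    if not (0.0 < fa < 90.0):
        raise ParameterError(f"fa must lie in (0, 90), got {fa}")
    signal = spgr_signal(phantom.m0, phantom.t1, fa, config.tr)
    sigma_frac = config.noise_sigma if noise_sigma is None else noise_sigma
    if sigma_frac < 0:
        raise ParameterError("noise_sigma must be >= 0")
    if sigma_frac > 0:
        fg = phantom.foreground
        sigma = sigma_frac * float(signal[fg].mean())
        if seed is None:
            seed = (config.seed, int(round(fa * 1000)))
        rng = np.random.default_rng(seed)
        signal = np.abs(signal + rng.normal(0.0, sigma, size=signal.shape))
    return signal


def simulate_asl_pair(
    phantom: TissuePhantom,
    config: AcquisitionConfig,
    schedule: BSSchedule,
    n_repeats: int = 1,
    physio_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate label/control volumes under a suppression schedule.

    Generative model (deliberately minimal):

    * static tissue signal = SPGR signal at ``fa_high`` scaled by the signed
      residual ``Mz/M0`` at readout for the voxel's T1;
    * the perfusion difference equals ``phantom.perfusion`` scaled by
      ``efficiency**n_pulses`` and the pulse-parity sign ``(-1)**n_pulses``;
    * per repeat and condition, the physiological fluctuation that imperfect
      suppression leaks into the subtraction enters twice: the static signal
      is multiplied by ``(1 + eps)`` with a global
      ``eps ~ Normal(0, physio_noise)``, and a spatially white leakage field
      with standard deviation ``physio_noise * mean(|static|)`` is added over
      the whole field of view (fluctuating unsuppressed magnetization smears
      across the image, raising the noise floor everywhere — perfectly
      suppressed tissue leaks nothing);
    * thermal noise per ``config.noise_sigma``.

    Volumes are kept signed (complex-difference convention) so the mean
    difference is an unbiased estimate of the scaled perfusion signal.

    Returns
    -------
    (labels, controls, mean_diff)
        Two ``(n_repeats, *shape)`` stacks and the voxelwise mean
        control-minus-label difference.
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    if physio_noise < 0:
        raise ParameterError("physio_noise must be >= 0")

    base = spgr_signal(phantom.m0, phantom.t1, config.fa_high, config.tr)
    fg = phantom.foreground
    residual = np.zeros(phantom.shape)
    if fg.any():
        residual[fg] = mz_at_readout(schedule, phantom.t1[fg])
    static = base * residual

    n = schedule.n_pulses
    parity_scale = ((-1.0) ** n) * schedule.inversion_efficiency**n
    perf_signal = phantom.perfusion * parity_scale

    sigma = config.noise_sigma * float(base[fg].mean()) if fg.any() else 0.0
    leak_sigma = physio_noise * float(np.abs(static).mean())
    rng = np.random.default_rng(seed)

    label_stack = np.empty((n_repeats,) + phantom.shape)
    control_stack = np.empty((n_repeats,) + phantom.shape)
    for r in range(n_repeats):
        eps_label, eps_control = rng.normal(0.0, physio_noise, size=2)
        leak_label = rng.normal(0.0, leak_sigma, size=phantom.shape)
        leak_control = rng.normal(0.0, leak_sigma, size=phantom.shape)
        noise_label = rng.normal(0.0, sigma, size=phantom.shape)
        noise_control = rng.normal(0.0, sigma, size=phantom.shape)
        label_stack[r] = static * (1.0 + eps_label) + leak_label + noise_label
        control_stack[r] = (
            static * (1.0 + eps_control) + perf_signal + leak_control + noise_control
        )
    mean_diff = (control_stack - label_stack).mean(axis=0)
    return label_stack, control_stack, mean_diff
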