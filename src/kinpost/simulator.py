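"""Dynamic-PET simulation with the simplified reference tissue model (SRTM).

This module generates everything the inference code consumes: the 54-frame
acquisition schedule, a deterministic reference-region time-activity curve
(TAC), noiseless target-region TACs obtained from the SRTM forward model,
frame-weighted Gaussian noise, Gaussian priors over the kinetic parameters
(DVR, k2, R1), training datasets of (parameters, noisy TAC) pairs, and the
relative-deviation-filtered test set used for evaluation.

The SRTM describes the target-region activity concentration ``C_T(t)`` in
terms of a reference-region curve ``C_R(t)`` and three parameters:

* ``DVR`` -- distribution volume ratio between target and reference region,
* ``k2``  -- efflux rate constant (min^-1),
* ``R1``  -- ratio of influx rate constants between the two regions,

via ``dC_T/dt = R1 dC_R/dt + k2 C_R - (k2/DVR) C_T``, whose solution is

``C_T = R1 C_R + (k2 - R1 k2 / DVR) * (C_R conv exp(-(k2/DVR) t))``.

All times are seconds internally; ``k2`` is stored in min^-1 (the field's
conventional unit) and converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "KineticParams",
    "ReferenceCurve",
    "Tac",
    "PriorSpec",
    "Dataset",
    "REF_CURVE_DEFAULTS",
    "build_frame_schedule",
    "make_reference_curve",
    "srtm_target_curve",
    "integrate_frames",
    "sample_noise_sigma",
    "add_noise",
    "noise_std_per_frame",
    "make_prior",
    "sample_prior",
    "select_test_set",
    "make_dataset",
    "forward_tac",
]

SECONDS_PER_MINUTE = 60.0

#: Default shape of the reference-region curve: a gamma-variate bolus plus a
#: slow washout component, C_R(t) = A (t/tau) exp(1 - t/tau)
#:                                + B (exp(-t/tau_wash) - exp(-t/tau_rise)).
#: The amplitude sets the activity scale of the whole simulation and therefore
#: the signal-to-noise ratio relative to the absolute noise scale sigma
#: (~1e-4); see docs/methods.md for how it was fixed.
REF_CURVE_DEFAULTS: dict[str, float] = {
    "bolus_amplitude": 0.2,
    "bolus_peak_time_s": 90.0,
    "washout_amplitude": 0.4,
    "washout_time_s": 4000.0,
    "rise_time_s": 90.0,
}


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame schedule: end times of consecutive frames (seconds)."""

    frame_end_times: np.ndarray

    def __post_init__(self) -> None:
        ends = np.asarray(self.frame_end_times, dtype=float)
        if ends.ndim != 1 or ends.size == 0:
            raise ValueError("frame_end_times must be a non-empty 1-D array")
        if not np.all(np.diff(np.concatenate(([0.0], ends))) > 0):
            raise ValueError("frame end times must be strictly increasing from 0")
        object.__setattr__(self, "frame_end_times", ends)

    @property
    def n_frames(self) -> int:
        return self.frame_end_times.size

    @property
    def frame_start_times(self) -> np.ndarray:
        return np.concatenate(([0.0], self.frame_end_times[:-1]))

    @property
    def frame_durations(self) -> np.ndarray:
        return np.diff(np.concatenate(([0.0], self.frame_end_times)))

    @property
    def total_duration(self) -> float:
        return float(self.frame_end_times[-1])


@dataclass(frozen=True)
class KineticParams:
    """One (DVR, k2, R1) triple; the unknown of the inverse problem."""

    dvr: float
    k2_per_min: float
    r1: float

    def __post_init__(self) -> None:
        if not (self.dvr > 0):
            raise ValueError(f"DVR must be > 0, got {self.dvr}")
        if not (self.k2_per_min >= 0):
            raise ValueError(f"k2 must be >= 0, got {self.k2_per_min}")
        if not (self.r1 > 0):
            raise ValueError(f"R1 must be > 0, got {self.r1}")

    def as_array(self) -> np.ndarray:
        return np.array([self.dvr, self.k2_per_min, self.r1])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "KineticParams":
        return cls(dvr=float(x[0]), k2_per_min=float(x[1]), r1=float(x[2]))


#: Order of parameters wherever they appear as a length-3 vector.
PARAM_NAMES = ("DVR", "k2_per_min", "R1")


@dataclass(frozen=True)
class ReferenceCurve:
    """Reference-region activity on a dense, uniform time grid (seconds)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t[0] != 0.0:
            raise ValueError("reference grid must start at t = 0")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0]):
            raise ValueError("reference grid must be uniform")
        if v[0] != 0.0:
            raise ValueError("reference curve must vanish at injection (t = 0)")
        if np.any(v < 0):
            raise ValueError("reference curve must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def grid_step(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class Tac:
    """A measured (or clean) TAC: per-frame integrals of activity."""

    values: np.ndarray
    schedule: FrameSchedule
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"TAC length {v.shape} does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        object.__setattr__(self, "values", v)

    @property
    def is_noisy(self) -> bool:
        return self.noise_sigma is not None


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors (location, scale) per kinetic parameter.

    Scales are standard deviations.  Draws are rejection-truncated to the
    physically admissible region DVR > 0, k2 >= 0, R1 > 0.
    """

    means: np.ndarray
    stds: np.ndarray
    setting: int

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.stds, dtype=float)
        if m.shape != (3,) or s.shape != (3,):
            raise ValueError("means and stds must have shape (3,)")
        if np.any(s <= 0):
            raise ValueError("prior scales must be > 0")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "stds", s)


@dataclass
class Dataset:
    """Paired (x, y) training or test data in array form.

    ``params`` has shape (n, 3) in the order (DVR, k2 [min^-1], R1); ``tacs``
    has shape (n, n_frames); ``sigmas`` holds the per-TAC realized noise scale.
    """

    params: np.ndarray
    tacs: np.ndarray
    sigmas: np.ndarray
    schedule: FrameSchedule
    prior: PriorSpec
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.params.shape[0]


def build_frame_schedule() -> FrameSchedule:
    """The fixed 54-frame schedule: 6x10 s, 8x15 s, 6x30 s, 8x60 s, 8x120 s, 18x300 s."""
    durations = np.concatenate(
        [
            np.full(6, 10.0),
            np.full(8, 15.0),
            np.full(6, 30.0),
            np.full(8, 60.0),
            np.full(8, 120.0),
            np.full(18, 300.0),
        ]
    )
    return FrameSchedule(frame_end_times=np.cumsum(durations))


def make_reference_curve(
    grid_step: float = 1.0,
    shape_params: dict[str, float] | None = None,
    total_duration: float | None = None,
) -> ReferenceCurve:
    """Deterministic reference-region curve on a uniform grid covering [0, T].

    The curve is a gamma-variate bolus plus a slow biexponential washout tail,
    a standard parametric shape for tracer kinetics in a region without
    specific binding: an early peak (within the first few minutes) followed by
    monotone washout.  Parameters default to :data:`REF_CURVE_DEFAULTS` so all
    experiments share one fixed curve.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    p = dict(REF_CURVE_DEFAULTS)
    if shape_params:
        unknown = set(shape_params) - set(p)
        if unknown:
            raise ValueError(f"unknown reference-curve parameters: {sorted(unknown)}")
        p.update(shape_params)
    if total_duration is None:
        total_duration = build_frame_schedule().total_duration
    n = int(round(total_duration / grid_step))
    t = np.arange(n + 1) * grid_step
    tau = p["bolus_peak_time_s"]
    bolus = p["bolus_amplitude"] * (t / tau) * np.exp(1.0 - t / tau)
    tail = p["washout_amplitude"] * (
        np.exp(-t / p["washout_time_s"]) - np.exp(-t / p["rise_time_s"])
    )
    return ReferenceCurve(times=t, values=bolus + tail)


def srtm_target_curve(params: KineticParams, ref: ReferenceCurve) -> np.ndarray:
    """Noiseless target-region curve C_T on the reference grid.

    Evaluates ``C_T = R1 C_R + (k2 - R1 k2/DVR) (C_R conv exp(-gamma t))``
    with ``gamma = k2/DVR`` (converted to s^-1).  The causal convolution is
    computed by an exponentially weighted trapezoidal recursion

        I[j] = e * I[j-1] + h/2 * (e * C_R[j-1] + C_R[j]),  e = exp(-gamma h),

    which is algebraically identical to trapezoidal quadrature of the
    convolution integral on the grid, and runs in O(n) via a linear filter.
    """
    gamma = (params.k2_per_min / params.dvr) / SECONDS_PER_MINUTE
    h = ref.grid_step
    cr = ref.values
    e = np.exp(-gamma * h)
    b = np.empty_like(cr)
    b[0] = 0.0
    b[1:] = 0.5 * h * (e * cr[:-1] + cr[1:])
    conv = lfilter([1.0], [1.0, -e], b)
    k2_s = params.k2_per_min / SECONDS_PER_MINUTE
    coeff = k2_s - params.r1 * k2_s / params.dvr
    return params.r1 * cr + coeff * conv


def integrate_frames(target_curve: np.ndarray, schedule: FrameSchedule,
                     ref: ReferenceCurve) -> Tac:
    """Clean TAC: trapezoidal integrals of the curve over each frame."""
    t = ref.times
    if t[-1] < schedule.total_duration - 1e-9:
        raise ValueError("curve grid does not span the full acquisition")
    if ref.grid_step > schedule.frame_durations.min():
        raise ValueError("curve grid is coarser than the shortest frame")
    cum = np.concatenate(([0.0], cumulative_trapezoid(target_curve, t)))
    ends = np.interp(schedule.frame_end_times, t, cum)
    starts = np.interp(schedule.frame_start_times, t, cum)
    return Tac(values=ends - starts, schedule=schedule)


def forward_tac(params: KineticParams, ref: ReferenceCurve,
                schedule: FrameSchedule) -> Tac:
    """Convenience composition: SRTM curve + frame integration (clean TAC)."""
    return integrate_frames(srtm_target_curve(params, ref), schedule, ref)


def sample_noise_sigma(rng: np.random.Generator) -> float:
    """Draw the per-TAC noise scale sigma ~ 1e-4 * Gamma(shape=1, scale=1)."""
    return 1e-4 * float(rng.gamma(shape=1.0, scale=1.0))


def noise_std_per_frame(sigma: float, schedule: FrameSchedule,
                        duration_exponent: float = 0.5) -> np.ndarray:
    """Per-frame noise standard deviation sigma * (dt_n / T) ** exponent.

    The default exponent 1/2 makes the noise standard deviation proportional
    to the square root of the frame's share of the total scan time, consistent
    with counting statistics on frame integrals.
    """
    frac = schedule.frame_durations / schedule.total_duration
    return sigma * frac**duration_exponent


def add_noise(clean: Tac, sigma: float, rng: np.random.Generator,
              duration_exponent: float = 0.5) -> Tac:
    """Add independent Gaussian noise e_n ~ N(0, (sigma (dt_n/T)^p)^2) per frame."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    std = noise_std_per_frame(sigma, clean.schedule, duration_exponent)
    noisy = clean.values + rng.normal(0.0, 1.0, size=clean.values.shape) * std
    return Tac(values=noisy, schedule=clean.schedule, noise_sigma=sigma)


#: Baseline prior (setting 1): location and scale per parameter.
_PRIOR_BASE_MEANS = np.array([1.0, 0.0006, 0.74])
_PRIOR_BASE_STDS = np.array([1.0, 0.01, 1.0])


def make_prior(setting: int = 1) -> PriorSpec:
    """The four prior settings.

    Setting 1 is the baseline (DVR ~ N(1.0, sd 1.0), k2 ~ N(0.0006, sd 0.01)
    min^-1, R1 ~ N(0.74, sd 1.0)); setting 2 scales the means by 1.2,
    setting 3 scales the variances by 1.2 (standard deviations by sqrt(1.2)),
    setting 4 scales both.
    """
    if setting not in (1, 2, 3, 4):
        raise ValueError(f"prior setting must be 1, 2, 3 or 4, got {setting!r}")
    means = _PRIOR_BASE_MEANS.copy()
    stds = _PRIOR_BASE_STDS.copy()
    if setting in (2, 4):
        means = means * 1.2
    if setting in (3, 4):
        stds = stds * np.sqrt(1.2)
    return PriorSpec(means=means, stds=stds, setting=setting)


def _in_support(draws: np.ndarray) -> np.ndarray:
    return (draws[:, 0] > 0) & (draws[:, 1] >= 0) & (draws[:, 2] > 0)


def sample_prior(prior: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. prior draws, rejection-truncated to DVR > 0, k2 >= 0, R1 > 0.

    Returns an (n, 3) array in the order (DVR, k2 [min^-1], R1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty((0, 3))
    while out.shape[0] < n:
        batch = rng.normal(prior.means, prior.stds, size=(max(n, 256), 3))
        out = np.vstack([out, batch[_in_support(batch)]])
    return out[:n]


def select_test_set(prior: PriorSpec, alpha: float = 0.26, m: int = 200,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Test parameters: prior draws kept iff |x_i - loc_i| / loc_i < alpha for all i.

    The filter concentrates the test set around the prior location vector; the
    default relative half-width is alpha = 0.26.  Returns an (m, 3) array.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0 (the acceptance region is empty)")
    if m < 1:
        raise ValueError("m must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    loc = prior.means
    out = np.empty((0, 3))
    while out.shape[0] < m:
        draws = sample_prior(prior, 8192, rng)
        keep = np.all(np.abs(draws - loc) / np.abs(loc) < alpha, axis=1)
        out = np.vstack([out, draws[keep]])
    return out[:m]


def make_dataset(
    prior: PriorSpec,
    n: int,
    rng: np.random.Generator,
    ref: ReferenceCurve | None = None,
    schedule: FrameSchedule | None = None,
    duration_exponent: float = 0.5,
    noiseless: bool = False,
    params: np.ndarray | None = None,
    seed: int | None = None,
) -> Dataset:
    """Generate n paired samples (x, noisy TAC) under a prior setting.

    For each x drawn from the truncated prior, a fresh sigma is drawn, the
    clean TAC is computed through the SRTM forward model and frame
    integration, and frame-weighted Gaussian noise is added.  Passing
    ``params`` overrides the prior draws (used for test sets).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if schedule is None:
        schedule = build_frame_schedule()
    if ref is None:
        ref = make_reference_curve(total_duration=schedule.total_duration)
    if params is None:
        params = sample_prior(prior, n, rng)
    else:
        params = np.asarray(params, dtype=float)
        if params.shape != (n, 3):
            raise ValueError(f"params must have shape ({n}, 3)")
    tacs = np.empty((n, schedule.n_frames))
    sigmas = np.empty(n)
    for i in range(n):
        kp = KineticParams.from_array(params[i])
        clean = forward_tac(kp, ref, schedule)
        if noiseless:
            sigmas[i] = 0.0
            tacs[i] = clean.values
        else:
            sigmas[i] = sample_noise_sigma(rng)
            tacs[i] = add_noise(clean, sigmas[i], rng, duration_exponent).values
    return Dataset(
        params=params,
        tacs=tacs,
        sigmas=sigmas,
        schedule=schedule,
        prior=prior,
        seed=seed,
        meta={"duration_exponent": duration_exponent, "noiseless": noiseless},
    )
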