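"""Random-walk Metropolis–Hastings reference sampler for SRTM posteriors.

The sampler targets the unnormalized posterior

    log p(x | y) = log p(y | x) + log p(x) + const,

with a Gaussian likelihood whose per-frame standard deviation is
``sigma * sqrt(dt_n / T)`` (matching the simulator's noise model) and a
truncated-Gaussian prior (density zero outside DVR > 0, k2 >= 0, R1 > 0).
Proposals are symmetric Gaussians with a diagonal covariance; the diagonal
scales are adapted during a pilot phase only and frozen before any retained
sample is drawn, so the retained chain has the correct stationary law.

Because the noise scale is small relative to the activity amplitude, SRTM
posteriors here are sharply peaked; the chain is started from a deterministic
MAP point (Nelder–Mead from the prior location) so burn-in is spent exploring
the typical set rather than travelling to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .simulator import (
    FrameSchedule,
    KineticParams,
    PriorSpec,
    ReferenceCurve,
    Tac,
    build_frame_schedule,
    forward_tac,
    make_reference_curve,
    noise_std_per_frame,
)

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "SrtmLogPosterior",
    "log_posterior_unnorm",
    "run_mh",
    "tune_proposal",
    "convergence_check",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Run-length and proposal settings for the random-walk MH sampler."""

    n_iterations: int = 60_000
    n_burn_in: int = 15_000
    proposal_scales: np.ndarray | None = None
    target_acceptance: tuple[float, float] = (0.2, 0.5)

    def __post_init__(self) -> None:
        if self.n_burn_in >= self.n_iterations:
            raise ValueError("n_burn_in must be < n_iterations")
        if self.proposal_scales is not None:
            s = np.asarray(self.proposal_scales, dtype=float)
            if np.any(s <= 0):
                raise ValueError("proposal scales must be > 0")
            object.__setattr__(self, "proposal_scales", s)

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_burn_in


@dataclass
class PosteriorSamples:
    """Posterior draws, (n, d) with d = 3 (DVR, k2 [min^-1], R1) for SRTM.

    Toy-target validation runs may carry other dimensions.
    """

    samples: np.ndarray
    source: str
    acceptance_rate: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[0] < 1:
            raise ValueError("samples must be a (n >= 1, d) array")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        self.samples = s

    @property
    def n(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter gap between early and late post-burn-in segment means."""

    gaps: np.ndarray
    threshold: float = 0.001

    @property
    def passed(self) -> np.ndarray:
        return self.gaps < self.threshold

    @property
    def all_passed(self) -> bool:
        return bool(np.all(self.passed))


class SrtmLogPosterior:
    """Cached unnormalized log-posterior for one measured TAC.

    Precomputes the reference curve context and per-frame noise variances so
    repeated evaluation inside the chain costs one O(grid) forward solve.
    """

    def __init__(
        self,
        y: Tac,
        sigma: float,
        prior: PriorSpec,
        ref: ReferenceCurve | None = None,
        schedule: FrameSchedule | None = None,
        duration_exponent: float = 0.5,
    ) -> None:
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.y = np.asarray(y.values, dtype=float)
        self.schedule = schedule or y.schedule
        self.ref = ref if ref is not None else make_reference_curve(
            total_duration=self.schedule.total_duration
        )
        self.prior = prior
        self.sigma = float(sigma)
        std = noise_std_per_frame(self.sigma, self.schedule, duration_exponent)
        self._inv_var = 1.0 / std**2
        self._log_norm = -0.5 * np.sum(np.log(2.0 * np.pi * std**2))

    def in_support(self, x: np.ndarray) -> bool:
        return bool(x[0] > 0 and x[1] >= 0 and x[2] > 0)

    def __call__(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if not self.in_support(x):
            return -np.inf
        clean = forward_tac(
            KineticParams.from_array(x), self.ref, self.schedule
        ).values
        resid = self.y - clean
        loglik = self._log_norm - 0.5 * np.dot(resid * self._inv_var, resid)
        # Truncation renormalization of the prior is x-independent, so the
        # plain Gaussian log-density suffices for MH ratios.
        z = (x - self.prior.means) / self.prior.stds
        logprior = -0.5 * np.dot(z, z)
        return float(loglik + logprior)

    def map_point(self, x0: np.ndarray | None = None) -> np.ndarray:
        """Deterministic posterior mode estimate (Nelder–Mead from x0)."""
        if x0 is None:
            x0 = self.prior.means.copy()
            x0[x0 <= 0] = 1e-6
        res = minimize(
            lambda x: -self(x),
            x0,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-10,
                     "adaptive": True},
        )
        return res.x if self.in_support(res.x) else np.asarray(x0, dtype=float)

    def laplace_scales(self, x_map: np.ndarray) -> np.ndarray | None:
        """Posterior stds from the inverse Hessian at the mode, or None.

        Central-difference Hessian of the negative log posterior; used to
        shape the random-walk proposal so all three parameters mix on their
        own posterior scale.
        """
        x_map = np.asarray(x_map, dtype=float)
        h = np.maximum(1e-7, 1e-5 * np.abs(x_map))
        hess = np.empty((3, 3))
        for i in range(3):
            for j in range(i, 3):
                xpp = x_map.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = x_map.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x_map.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x_map.copy(); xmm[[i, j]] -= [h[i], h[j]]
                val = -(self(xpp) - self(xpm) - self(xmp) + self(xmm)) / (
                    4.0 * h[i] * h[j]
                )
                hess[i, j] = hess[j, i] = val
        if not np.all(np.isfinite(hess)):
            return None
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return None
        return np.sqrt(diag)


def log_posterior_unnorm(
    x,
    y: Tac,
    sigma: float,
    prior: PriorSpec,
    ref: ReferenceCurve | None = None,
    schedule: FrameSchedule | None = None,
    duration_exponent: float = 0.5,
) -> float:
    """Unnormalized log-posterior of kinetic parameters x given a noisy TAC y.

    Functional wrapper over :class:`SrtmLogPosterior`; returns ``-inf``
    (never raises) for x outside the truncated support.
    """
    if isinstance(x, KineticParams):
        x = x.as_array()
    lp = SrtmLogPosterior(y, sigma, prior, ref, schedule, duration_exponent)
    return lp(np.asarray(x, dtype=float))


def _mh_chain(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    scales: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Plain random-walk MH loop; returns (chain, acceptance_rate)."""
    d = x0.size
    chain = np.empty((n_iter, d))
    x = np.asarray(x0, dtype=float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initialization point has zero posterior density")
    steps = rng.normal(size=(n_iter, d)) * scales
    logu = np.log(rng.uniform(size=n_iter))
    n_acc = 0
    for i in range(n_iter):
        prop = x + steps[i]
        lp_prop = log_post(prop)
        if lp_prop - lp > logu[i]:
            x, lp = prop, lp_prop
            n_acc += 1
        chain[i] = x
    return chain, n_acc / n_iter


def tune_proposal(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    init_scales: np.ndarray,
    rng: np.random.Generator,
    target_band: tuple[float, float] = (0.2, 0.5),
    pilot_length: int = 400,
    max_rounds: int = 60,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Adapt diagonal proposal scales during a pilot phase.

    Multiplicative stochastic-approximation updates on a global factor drive
    the pilot acceptance rate into ``target_band``; once roughly in band the
    per-parameter shape is re-estimated from the pilot draws and the factor
    re-tuned.  Returns ``(scales, last_state, last_acceptance)``; the scales
    are frozen for the retained run.
    """
    if pilot_length < 100:
        raise ValueError("pilot_length must be >= 100")
    scales = np.asarray(init_scales, dtype=float).copy()
    x = np.asarray(x0, dtype=float).copy()
    lo, hi = target_band
    mid = 0.5 * (lo + hi)
    acc = np.nan
    best = (np.inf, scales.copy(), x.copy(), np.nan)
    reshaped = False
    for rnd in range(max_rounds):
        pilot, acc = _mh_chain(log_post, x, scales, pilot_length, rng)
        x = pilot[-1]
        miss = abs(acc - mid)
        if miss < best[0]:
            best = (miss, scales.copy(), x.copy(), acc)
        if lo <= acc <= hi:
            if reshaped:
                return scales, x, acc
            # Re-estimate the per-parameter shape from in-band pilot draws,
            # keeping the overall magnitude, then fine-tune the factor.
            spread = pilot[pilot_length // 2 :].std(axis=0)
            if np.all(spread > 0):
                shape = spread / np.exp(np.mean(np.log(spread)))
                scales = shape * np.exp(np.mean(np.log(scales)))
            reshaped = True
            continue
        # Multiplicative update: acceptance too high -> larger steps.
        scales = scales * np.exp(2.0 * (acc - mid))
    warnings.warn(
        f"proposal tuning did not reach the acceptance band after "
        f"{max_rounds} rounds (best acceptance {best[3]:.3f})",
        RuntimeWarning,
        stacklevel=2,
    )
    _, scales, x, acc = best
    return scales, x, acc


def run_mh(
    y: Tac,
    sigma: float,
    prior: PriorSpec,
    config: MCMCConfig | None = None,
    rng: np.random.Generator | None = None,
    ref: ReferenceCurve | None = None,
    schedule: FrameSchedule | None = None,
    duration_exponent: float = 0.5,
    log_post: Callable[[np.ndarray], float] | None = None,
    x0: np.ndarray | None = None,
) -> PosteriorSamples:
    """Sample the SRTM posterior for one TAC by random-walk MH.

    If ``config.proposal_scales`` is ``None`` the scales are adapted in a
    pilot phase (and the main chain starts from the pilot's last state);
    otherwise the given scales are used as-is.  The first ``n_burn_in`` states
    of the main chain are discarded.  ``log_post`` may override the target
    (used by toy-problem validation tests); then ``x0`` must be given.
    """
    config = config or MCMCConfig()
    rng = rng or np.random.default_rng()
    if log_post is None:
        lp_obj = SrtmLogPosterior(y, sigma, prior, ref, schedule,
                                  duration_exponent)
        log_post = lp_obj
        if x0 is None:
            x0 = lp_obj.map_point()
        if config.proposal_scales is not None:
            init_scales = config.proposal_scales
        else:
            # Shape the proposal on the posterior's own scale (Laplace
            # approximation at the mode, 2.38/sqrt(d) step rule), falling
            # back to a prior-scale guess that the pilot phase then adapts.
            lap = lp_obj.laplace_scales(np.asarray(x0, dtype=float))
            init_scales = (
                (2.38 / np.sqrt(3.0)) * lap if lap is not None
                else 0.05 * prior.stds
            )
    else:
        if x0 is None:
            raise ValueError("x0 is required with a custom log_post")
        x0 = np.asarray(x0, dtype=float)
        init_scales = (
            config.proposal_scales
            if config.proposal_scales is not None
            else np.ones(x0.size)
        )
    if config.proposal_scales is None:
        scales, x0, _ = tune_proposal(
            log_post, x0, init_scales, rng, config.target_acceptance
        )
    else:
        scales = np.asarray(config.proposal_scales, dtype=float)
    chain, acc = _mh_chain(log_post, x0, scales, config.n_iterations, rng)
    retained = chain[config.n_burn_in :]
    return PosteriorSamples(
        samples=retained,
        source="mcmc",
        acceptance_rate=acc,
        provenance={
            "n_iterations": config.n_iterations,
            "n_burn_in": config.n_burn_in,
            "proposal_scales": scales.tolist(),
            "sigma": sigma,
            "full_chain": chain,
        },
    )


def convergence_check(
    chain: np.ndarray, burn_in: int = 0, threshold: float = 0.001
) -> ConvergenceReport:
    """Early-vs-late segment-mean gap, computed after discarding burn-in.

    For each parameter trace the gap is ``|mean(first 10%) - mean(last 50%)|``
    of the post-burn-in samples; a gap below ``threshold`` indicates the chain
    has reached its stationary regime.
    """
    chain = np.atleast_2d(np.asarray(chain, dtype=float))
    if chain.shape[0] == 1 and chain.shape[1] > 3:
        chain = chain.T
    if burn_in >= chain.shape[0]:
        raise ValueError("burn_in must be smaller than the chain length")
    post = chain[burn_in:]
    n = post.shape[0]
    first = post[: max(1, n // 10)].mean(axis=0)
    last = post[-max(1, n // 2) :].mean(axis=0)
    return ConvergenceReport(gaps=np.abs(first - last), threshold=threshold)
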