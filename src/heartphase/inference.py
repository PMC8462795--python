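"""Bayesian fitting of the six-parameter model and day-to-day phase tracking.

Each 2-day fit window is sampled with Goodman & Weare's affine-invariant
ensemble MCMC (the stretch move).  The phase ``c`` is treated as a circular
parameter: summarised by its circular mean, with central 80% intervals taken
around it, and (when tracking successive days) given a wrapped-Gaussian
prior of s.d. 1 h centred on the previous night's estimate, so that only
the prior — never the likelihood — links consecutive windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GapSeries, ModelParams, PARAM_NAMES, ar1_loglik, ar1_loglik_batch
from .preprocess import FitWindow

__all__ = [
    "PriorSpec",
    "PosteriorSummary",
    "PhaseEntry",
    "PhaseTrack",
    "SamplerStuckError",
    "wrap_half_day",
    "circular_mean_hours",
    "log_posterior",
    "run_ensemble",
    "fit_window",
    "track_phases",
    "pacf_with_bounds",
]

log = logging.getLogger(__name__)

#: uniform prior box; wide margins around the cohort-typical histograms
DEFAULT_BOUNDS = {
    "a": (30.0, 120.0),
    "b": (0.0, 20.0),
    "d": (0.0, 2.0),
    "sigma": (0.5, 30.0),
    "k": (0.0, 0.999),
}

SEQUENTIAL_PHASE_SD_H = 1.0  # s.d. of the day-to-day phase prior, hours


def wrap_half_day(x):
    """Wrap hour differences into (-12, 12]."""
    return -((-np.asarray(x, dtype=float) + 12.0) % 24.0 - 12.0)


def circular_mean_hours(hours: np.ndarray) -> float:
    """Resultant-vector mean of clock hours, result in [0, 24)."""
    ang = np.asarray(hours, dtype=float) * (2.0 * np.pi / 24.0)
    m = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return (m * 24.0 / (2.0 * np.pi)) % 24.0


@dataclass(frozen=True)
class PriorSpec:
    """Uniform box on (a, b, d, sigma, k); flat or wrapped-Gaussian prior on c.

    c_prior, when present, is (mean hour, s.d. hours) evaluated circularly:
    the density depends only on the wrapped difference to the mean.
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    c_prior: Optional[tuple[float, float]] = None

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
        if self.c_prior is not None and not self.c_prior[1] > 0:
            raise ValueError("c-prior s.d. must be > 0")

    def with_c_prior(self, mean: float, sd: float = SEQUENTIAL_PHASE_SD_H) -> "PriorSpec":
        return replace(self, c_prior=(float(mean) % 24.0, float(sd)))

    def log_prior_batch(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = np.zeros(theta.shape[0])
        for i, name in enumerate(PARAM_NAMES):
            if name == "c":
                continue
            lo, hi = self.bounds[name]
            lp[(theta[:, i] < lo) | (theta[:, i] > hi)] = -np.inf
        if self.c_prior is not None:
            mu, sd = self.c_prior
            dev = wrap_half_day(theta[:, 2] - mu)
            lp += -0.5 * (dev / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))
        return lp

    def sample_initial(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Walker cloud: uniform in the box (slightly inset), c from its prior."""
        theta = np.empty((n, 6))
        for i, name in enumerate(PARAM_NAMES):
            if name == "c":
                continue
            lo, hi = self.bounds[name]
            pad = 0.01 * (hi - lo)
            theta[:, i] = rng.uniform(lo + pad, hi - pad, size=n)
        if self.c_prior is not None:
            mu, sd = self.c_prior
            theta[:, 2] = rng.normal(mu, sd, size=n)
        else:
            theta[:, 2] = rng.uniform(0.0, 24.0, size=n)
        return theta


def log_posterior(params: ModelParams, obs: GapSeries, prior: PriorSpec) -> float:
    """Sum of the AR(1) log-likelihood and the prior log-density."""
    lp = float(prior.log_prior_batch(params.to_array()[None, :])[0])
    if not np.isfinite(lp):
        return -np.inf
    return lp + ar1_loglik(params, obs)


def _make_log_posterior_batch(obs: GapSeries, prior: PriorSpec) -> Callable:
    def f(theta: np.ndarray) -> np.ndarray:
        lp = prior.log_prior_batch(theta)
        ok = np.isfinite(lp)
        if np.any(ok):
            lp[ok] += ar1_loglik_batch(np.atleast_2d(theta)[ok], obs)
        return lp
    return f


# ---------------------------------------------------------------------------
# affine-invariant ensemble sampler (stretch move)
# ---------------------------------------------------------------------------

class SamplerStuckError(RuntimeError):
    """All walkers rejected every proposal over a diagnostic window."""


def run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    n_total_samples: int = 100_000,
    stretch_a: float = 2.0,
    seed: int | np.random.Generator = 0,
    burn_frac: float = 0.2,
    stuck_window: int = 50,
) -> tuple[np.ndarray, float]:
    """Sample ``log_prob`` with the stretch move; return post-burn-in chain.

    ``log_prob`` maps an (n, dim) stack of positions to (n,) log-densities.
    One walker ``i`` is moved along the line through a randomly chosen other
    walker ``j``: the proposal is ``p_j + z (p_i - p_j)`` with
    ``z ~ g(z) ∝ 1/sqrt(z)`` on [1/a, a], accepted with probability
    ``min(1, z**(dim-1) * exp(Δ log_prob))``.  Walkers are updated in two
    half-ensembles so each proposal uses only fixed complementary walkers.

    Returns (chain of shape (n_kept_sweeps, n_walkers, dim), acceptance rate).
    Fully reproducible from ``seed``.
    """
    if stretch_a <= 1.0:
        raise ValueError("stretch_a must be > 1 (a=1 makes z≡1 and the chain never moves)")
    init = np.array(init, dtype=float)
    n_walkers, dim = init.shape
    if n_walkers < 2 * dim + 2:
        raise ValueError(f"need at least {2 * dim + 2} walkers for dim={dim}")
    if n_walkers % 2:
        raise ValueError("n_walkers must be even")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lp = log_prob(init)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial walker positions must have finite log-probability")

    n_sweeps = max(1, math.ceil(n_total_samples / n_walkers))
    x = init
    chain = np.empty((n_sweeps, n_walkers, dim))
    half = n_walkers // 2
    groups = (np.arange(half), np.arange(half, n_walkers))
    n_acc = 0
    n_prop = 0
    acc_recent = 0

    for s in range(n_sweeps):
        for g in (0, 1):
            active, other = groups[g], groups[1 - g]
            na = len(active)
            j = rng.integers(0, len(other), size=na)
            u = rng.random(na)
            z = ((stretch_a - 1.0) * u + 1.0) ** 2 / stretch_a
            xo = x[other][j]
            prop = xo + z[:, None] * (x[active] - xo)
            lp_prop = log_prob(prop)
            log_alpha = (dim - 1) * np.log(z) + lp_prop - lp[active]
            acc = np.log(rng.random(na)) < log_alpha
            x[active[acc]] = prop[acc]
            lp[active[acc]] = lp_prop[acc]
            n_acc += int(acc.sum())
            acc_recent += int(acc.sum())
            n_prop += na
        chain[s] = x
        if (s + 1) % stuck_window == 0:
            if acc_recent == 0:
                raise SamplerStuckError(
                    f"no proposal accepted in {stuck_window} sweeps (sweep {s + 1})"
                )
            acc_recent = 0

    n_burn = int(burn_frac * n_sweeps)
    return chain[n_burn:], n_acc / n_prop


def _ess(chain: np.ndarray) -> float:
    """Crude effective sample size: Geyer initial-positive-sequence estimate
    applied to each parameter's walker-averaged trace, minimum over params."""
    n_sweeps, n_walkers, dim = chain.shape
    if n_sweeps < 8:
        return float(n_sweeps * n_walkers)
    ess_min = np.inf
    for p in range(dim):
        trace = chain[:, :, p].mean(axis=1)
        v = trace - trace.mean()
        var = np.dot(v, v) / n_sweeps
        if var == 0:
            continue
        acf = np.correlate(v, v, mode="full")[n_sweeps - 1 :] / (n_sweeps * var)
        tau = 1.0
        for lag in range(1, min(n_sweeps // 2, 200), 2):
            pair = acf[lag] + acf[lag + 1] if lag + 1 < len(acf) else acf[lag]
            if pair < 0:
                break
            tau += 2.0 * pair
        ess_min = min(ess_min, n_sweeps * n_walkers / tau)
    return float(ess_min if np.isfinite(ess_min) else n_sweeps * n_walkers)


# ---------------------------------------------------------------------------
# posterior summaries and per-window fits
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Point estimates and central 80% intervals for the six parameters.

    ``c`` is summarised by its circular mean; its interval is the central
    10th–90th percentile of wrapped deviations about that mean, so the
    endpoints may fall outside [0, 24) but always satisfy lo < mean < hi.
    """

    point: ModelParams
    intervals: dict
    n_samples: int
    ess: float
    acceptance: float

    @property
    def phase(self) -> float:
        return self.point.c

    @property
    def phase_interval(self) -> tuple[float, float]:
        return self.intervals["c"]


def summarize_samples(flat: np.ndarray, acceptance: float = np.nan,
                      ess: float = np.nan) -> PosteriorSummary:
    """Posterior summary of a flat (n, 6) sample cloud."""
    est = {}
    intervals = {}
    for i, name in enumerate(PARAM_NAMES):
        s = flat[:, i]
        if name == "c":
            m = circular_mean_hours(s)
            dev = wrap_half_day(s - m)
            lo, hi = np.percentile(dev, [10, 90])
            est[name] = m
            intervals[name] = (m + lo, m + hi)
        else:
            est[name] = float(np.mean(s))
            intervals[name] = tuple(np.percentile(s, [10, 90]))
    return PosteriorSummary(
        point=ModelParams(**est),
        intervals=intervals,
        n_samples=flat.shape[0],
        ess=ess,
        acceptance=acceptance,
    )


def fit_window(
    window: FitWindow | GapSeries,
    prior: PriorSpec | None = None,
    n_total_samples: int = 100_000,
    n_walkers: int = 32,
    seed: int | np.random.Generator = 0,
    return_samples: bool = False,
):
    """Fit the six parameters of one 2-day window by ensemble MCMC.

    Returns a PosteriorSummary (and, if requested, the flat post-burn-in
    sample cloud).  The first 20% of sweeps are discarded as burn-in.
    """
    prior = prior or PriorSpec()
    obs = window.to_gap_series() if isinstance(window, FitWindow) else window
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = _make_log_posterior_batch(obs, prior)
    init = prior.sample_initial(n_walkers, rng)
    # nudge any zero-likelihood starts toward the prior-box centre
    lp0 = target(init)
    tries = 0
    while not np.all(np.isfinite(lp0)) and tries < 50:
        bad = ~np.isfinite(lp0)
        init[bad] = 0.5 * (init[bad] + init[~bad][rng.integers(0, (~bad).sum(), bad.sum())])
        lp0 = target(init)
        tries += 1
    if not np.all(np.isfinite(lp0)):
        raise SamplerStuckError("could not find finite-probability starting points")
    chain, acc = run_ensemble(target, init, n_total_samples=n_total_samples, seed=rng)
    flat = chain.reshape(-1, chain.shape[-1])
    summary = summarize_samples(flat, acceptance=acc, ess=_ess(chain))
    if return_samples:
        return summary, flat
    return summary


# ---------------------------------------------------------------------------
# sequential phase tracking
# ---------------------------------------------------------------------------

@dataclass
class PhaseEntry:
    """One night: sleep midpoint, phase posterior, and phase difference."""

    midpoint: pd.Timestamp
    phase_h: float
    ci80: tuple[float, float]
    phase_difference_h: float
    summary: Optional[PosteriorSummary] = None


@dataclass
class PhaseTrack:
    """Dated sequence of nightly phase posteriors.

    phase_difference = wrap(c − sleep-midpoint clock hour) ∈ (−12, 12]:
    +4 means the HR minimum falls 4 h after the midpoint of sleep.
    """

    entries: list[PhaseEntry]

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def phases(self) -> np.ndarray:
        return np.array([e.phase_h for e in self.entries])

    @property
    def midpoints(self) -> list[pd.Timestamp]:
        return [e.midpoint for e in self.entries]

    @property
    def phase_differences(self) -> np.ndarray:
        return np.array([e.phase_difference_h for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [e.midpoint for e in self.entries],
                "phase_mean_h": [e.phase_h for e in self.entries],
                "ci80_lo": [e.ci80[0] for e in self.entries],
                "ci80_hi": [e.ci80[1] for e in self.entries],
                "sleep_midpoint_h": [
                    e.midpoint.hour + e.midpoint.minute / 60 + e.midpoint.second / 3600
                    for e in self.entries
                ],
                "phase_difference_h": [e.phase_difference_h for e in self.entries],
            }
        )


def phase_difference(c_hours: float, midpoint: pd.Timestamp) -> float:
    mid_h = midpoint.hour + midpoint.minute / 60.0 + midpoint.second / 3600.0
    return float(wrap_half_day(c_hours - mid_h))


def track_phases(
    windows: Sequence[FitWindow],
    base_prior: PriorSpec | None = None,
    n_total_samples: int = 100_000,
    n_walkers: int = 32,
    seed: int = 0,
    phase_prior_sd: float | None = SEQUENTIAL_PHASE_SD_H,
) -> PhaseTrack:
    """Fit windows in time order, chaining each fit's phase into the next.

    Window 1 is fit under ``base_prior`` (flat in c); every later window
    gets a circular Gaussian c-prior (s.d. 1 h) centred at the previous
    window's circular-mean phase.  Only the prior links windows — the
    likelihood of each window is untouched.  A failed window breaks the
    chain: the next window reverts to the base prior.  Setting
    ``phase_prior_sd`` to None (or infinity) disables the chaining, which
    makes the track identical to independent window fits.
    """
    if phase_prior_sd is not None and not np.isfinite(phase_prior_sd):
        phase_prior_sd = None
    base_prior = base_prior or PriorSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(windows))
    entries: list[PhaseEntry] = []
    prev_phase: float | None = None
    for w, cs in zip(windows, child_seeds):
        if prev_phase is None or phase_prior_sd is None:
            prior = base_prior
        else:
            prior = base_prior.with_c_prior(prev_phase, phase_prior_sd)
        try:
            summary = fit_window(
                w, prior, n_total_samples=n_total_samples,
                n_walkers=n_walkers, seed=np.random.default_rng(cs),
            )
        except SamplerStuckError as err:
            log.warning("window at %s failed (%s); chain reset", w.center_sleep.midpoint, err)
            prev_phase = None
            continue
        c = summary.phase
        entries.append(
            PhaseEntry(
                midpoint=w.center_sleep.midpoint,
                phase_h=c,
                ci80=summary.phase_interval,
                phase_difference_h=phase_difference(c, w.center_sleep.midpoint),
                summary=summary,
            )
        )
        prev_phase = c
    return PhaseTrack(entries)


# ---------------------------------------------------------------------------
# phase-difference analytics
# ---------------------------------------------------------------------------

def pacf_with_bounds(series: np.ndarray, max_lag: int = 15) -> tuple[np.ndarray, float]:
    """Partial autocorrelation via Durbin–Levinson with 95% null bounds.

    Returns (pacf for lags 0..max_lag, bound) where the two-sided
    significance bounds are ±z_{0.975}/sqrt(n); lags outside them indicate
    phase-difference memory beyond what white noise explains.
    """
    from scipy.stats import norm
    from statsmodels.tsa.stattools import pacf as sm_pacf

    x = np.asarray(series, dtype=float)
    if x.size <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    if np.ptp(x) == 0:
        raise ValueError("PACF undefined for a constant series")
    vals = sm_pacf(x, nlags=max_lag, method="ldb")
    bound = float(norm.ppf(0.975) / math.sqrt(x.size))
    return vals, bound
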