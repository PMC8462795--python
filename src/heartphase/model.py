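"""Six-parameter generative model of wakeful heart rate.

Heart rate at hour ``t`` of wakefulness is modelled as a 24-h cosinor plus a
linear effect of concurrent activity,

    HR_t = a - b * cos(pi/12 * (t - c)) + d * activity + eps_t,

where ``a`` is the basal heart rate (bpm), ``b`` the amplitude of the
circadian oscillation (bpm), ``c`` the clock time of the circadian HR
minimum (hours, the phase), ``d`` the HR increase per unit activity
(bpm per step/min), and the residual ``eps_t`` follows a stationary AR(1)
process: each 5-min step retains a fraction ``k`` of the previous residual
plus fresh Gaussian innovation of standard deviation ``sigma``.

The likelihood is the exact Gaussian density of the residuals observed on a
5-min grid with arbitrary gaps (sleep, device charging): a residual observed
``g`` bins after the previous one is conditionally
``N(k**g * r_prev, sigma**2 * (1 - k**(2g)) / (1 - k**2))``, and the first
residual is drawn from the stationary marginal ``N(0, sigma**2/(1-k**2))``.
Because the AR(1) process is Markov, no information is lost by skipping the
unobserved bins, which is what makes the fit insensitive to large gaps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "GapSeries",
    "mean_hr",
    "ar1_loglik",
    "ar1_loglik_batch",
    "decorrelation_time",
    "PARAM_NAMES",
]

PARAM_NAMES = ("a", "b", "c", "d", "sigma", "k")

#: grid resolution all observation times are assumed to sit on
DEFAULT_BIN_MINUTES = 5.0


@dataclass(frozen=True)
class ModelParams:
    """The six fitted physiological quantities.

    a : basal heart rate, bpm
    b : circadian amplitude, bpm (>= 0)
    c : clock time of the circadian HR minimum, hours in [0, 24)
    d : HR increase per unit activity, bpm per (steps/min)
    sigma : AR(1) innovation standard deviation, bpm (> 0)
    k : AR(1) carry-over fraction per 5-min bin, in [0, 1)
    """

    a: float
    b: float
    c: float
    d: float
    sigma: float
    k: float

    def __post_init__(self):
        object.__setattr__(self, "c", float(self.c) % 24.0)

    def validate(self) -> None:
        if self.b < 0:
            raise ValueError(f"amplitude b must be >= 0, got {self.b}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0.0 <= self.k < 1.0):
            raise ValueError(f"k must be in [0, 1), got {self.k}")

    def to_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.sigma, self.k])

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ModelParams":
        return cls(*(float(v) for v in theta))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls(**json.loads(s))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class GapSeries:
    """Observation vector of one fit window on the 5-min grid with gaps.

    t : hours since local midnight of the window's first day, strictly
        increasing, separated by positive integer multiples of the bin length
    y : observed heart rate, bpm
    x : activity covariate, steps per minute
    """

    t: np.ndarray
    y: np.ndarray
    x: np.ndarray
    bin_minutes: float = DEFAULT_BIN_MINUTES

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if not (t.shape == y.shape == x.shape) or t.ndim != 1:
            raise ValueError("t, y, x must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("empty observation series")
        dt_bins = np.diff(t) * 60.0 / self.bin_minutes
        if t.size > 1:
            g = np.rint(dt_bins)
            if np.any(g < 1) or np.any(np.abs(dt_bins - g) > 1e-6):
                raise ValueError(
                    "t must increase by positive integer multiples of the bin length"
                )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x", x)

    def __len__(self) -> int:
        return self.t.size

    @property
    def gaps(self) -> np.ndarray:
        """Separation of consecutive observations, in whole bins."""
        return np.rint(np.diff(self.t) * 60.0 / self.bin_minutes).astype(int)


def mean_hr(params: ModelParams, t, steps_per_min):
    """Deterministic part of the model: cosinor plus linear activity effect.

    24-h periodic in ``t``; at constant activity the minimum over ``t`` is at
    ``t = c (mod 24)`` with value ``a - b``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(steps_per_min, dtype=float)
    return params.a - params.b * np.cos(np.pi / 12.0 * (t - params.c)) + params.d * x


def _loglik_core(a, b, c, d, sigma, k, t, y, x, gaps):
    """AR(1) gap log-likelihood over a leading walker axis.

    Parameter arguments are shape (W, 1) arrays; t, y, x are shape (n,);
    gaps is shape (n-1,) of ints.  Returns shape (W,).
    """
    r = y - (a - b * np.cos(np.pi / 12.0 * (t - c)) + d * x)  # (W, n)
    sig2 = sigma[:, 0] ** 2
    one_minus_k2 = 1.0 - k[:, 0] ** 2
    # stationary marginal for the first residual
    var0 = sig2 / one_minus_k2
    ll = -0.5 * (np.log(2.0 * np.pi * var0) + r[:, 0] ** 2 / var0)
    if t.size > 1:
        kg = k**gaps  # (W, n-1): k^g per transition
        var = sig2[:, None] * (1.0 - kg**2) / one_minus_k2[:, None]
        innov = r[:, 1:] - kg * r[:, :-1]
        ll = ll - 0.5 * np.sum(np.log(2.0 * np.pi * var) + innov**2 / var, axis=-1)
    return ll


def ar1_loglik(params: ModelParams, obs: GapSeries) -> float:
    """Exact Gaussian log-likelihood of ``obs`` under the AR(1) cosinor model.

    Returns ``-inf`` (never raises) for ``sigma <= 0`` or ``k`` outside
    [0, 1) so that samplers can reject invalid proposals.
    """
    if not (params.sigma > 0.0) or not (0.0 <= params.k < 1.0) or params.b < 0.0:
        return -np.inf
    return float(ar1_loglik_batch(params.to_array()[None, :], obs)[0])


def ar1_loglik_batch(theta: np.ndarray, obs: GapSeries) -> np.ndarray:
    """Vectorised log-likelihood for a (W, 6) stack of parameter vectors.

    Rows violating the parameter constraints get ``-inf``.  Used by the
    ensemble sampler to evaluate all walkers of one half-ensemble at once.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    a, b, c, d, sigma, k = (theta[:, i : i + 1] for i in range(6))
    valid = (sigma[:, 0] > 0.0) & (k[:, 0] >= 0.0) & (k[:, 0] < 1.0) & (b[:, 0] >= 0.0)
    out = np.full(theta.shape[0], -np.inf)
    if not np.any(valid):
        return out
    sub = (v[valid] for v in (a, b, c, d, sigma, k))
    out[valid] = _loglik_core(*sub, obs.t, obs.y, obs.x, obs.gaps)
    return out


def decorrelation_time(k: float, bin_minutes: float = DEFAULT_BIN_MINUTES) -> float:
    """e-folding time of residual autocorrelation, ``-bin / ln k``, minutes.

    For the cohort-typical ``k = 0.9339`` per 5-min bin this is ~73 min,
    i.e. the correlated-error process forgets on a roughly 1-h timescale.
    """
    if not (0.0 < k < 1.0):
        raise ValueError(f"k must be in (0, 1), got {k}")
    return -bin_minutes / math.log(k)
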