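"""Personalized phase-response curve (PRC) of the heart-rate clock to activity.

For each day flanked by two nightly phase estimates, activity is re-indexed
by *relative hour* — hours after the estimated CRHR minimum of the previous
night — and totalled into 24 one-hour bins; the nightly phase shift
y = wrap(c_prev − c_next) (advances positive, delays negative) is the
response.  Ordinary least squares within each relative-hour bin gives the
average phase shift per step for activity at that circadian time; a
4-parameter asymmetric sinusoid (mean, amplitude, phase, trough-to-peak
time) is then fit to the 24 slopes.  The curve's zero-activity drift yields
the clock's intrinsic period as 24 − δ₀ hours.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .inference import PhaseTrack, wrap_half_day
from .preprocess import BinnedSeries

__all__ = [
    "PRCPointSet",
    "PRCFit",
    "collect_prc_points",
    "shuffle_control",
    "fit_bin_slopes",
    "asymmetric_wave",
    "fit_asymmetric_sinusoid",
    "period_from_offset",
    "prc_characteristics",
    "fit_prc",
    "prc_robustness_nonoverlap",
]

log = logging.getLogger(__name__)

N_BINS = 24

#: nights are "consecutive" when their midpoints are this many hours apart
CONSECUTIVE_NIGHT_RANGE_H = (16.0, 32.0)
NONOVERLAP_NIGHT_RANGE_H = (40.0, 56.0)


@dataclass
class PRCPointSet:
    """Per-relative-hour regression points.

    x[h] holds, for each usable day, the total steps taken in relative hour
    ``h`` (hours after the previous night's CRHR minimum); y holds that
    day's nightly phase shift in hours (advance positive).  Every day
    contributes one point to every bin (x may be 0), so y is shared across
    bins within a day.
    """

    x: list = field(default_factory=lambda: [[] for _ in range(N_BINS)])
    y: np.ndarray = field(default_factory=lambda: np.zeros(0))
    day_totals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_days(self) -> int:
        return len(self.y)

    def x_matrix(self) -> np.ndarray:
        """(n_days, 24) matrix of per-bin step totals."""
        return np.array(self.x).T

    def bin_mean_steps(self) -> np.ndarray:
        return self.x_matrix().mean(axis=0) if self.n_days else np.zeros(N_BINS)


@dataclass
class PRCFit:
    """24 binned slopes plus the fitted asymmetric sinusoid and derivatives.

    slopes are in hours of phase shift per step; offset/amplitude share
    those units; phase (the horizontal shift) and trough_to_peak are in
    relative hours.  intrinsic_period is in hours.
    """

    slopes: np.ndarray
    slope_se: np.ndarray
    n_points: np.ndarray
    offset: float
    amplitude: float
    phase: float
    trough_to_peak: float
    rss: float
    rss_mean_only: float
    bin_mean_steps: np.ndarray
    mean_shift_h: float              # mean nightly phase shift ȳ
    points: Optional["PRCPointSet"] = None
    intrinsic_period_h: float = np.nan
    sinusoidality: float = np.nan
    horizontal_shift: float = np.nan

    def curve(self, h) -> np.ndarray:
        return self.offset + self.amplitude * asymmetric_wave(
            np.asarray(h, float), self.phase, self.trough_to_peak
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_hour": np.arange(N_BINS),
                "slope_h_per_step": self.slopes,
                "slope_se": self.slope_se,
                "n_points": self.n_points,
            }
        )

    def curve_json(self) -> str:
        return json.dumps(
            {
                "offset": self.offset,
                "amplitude": self.amplitude,
                "phase": self.phase,
                "trough_to_peak": self.trough_to_peak,
                "period_h": self.intrinsic_period_h,
                "sinusoidality": self.sinusoidality,
            }
        )


# ---------------------------------------------------------------------------
# point collection
# ---------------------------------------------------------------------------

def _collect(track: PhaseTrack, binned: BinnedSeries, night_range: tuple) -> PRCPointSet:
    lo, hi = night_range
    points = PRCPointSet()
    ys, totals = [], []
    step_totals = binned.steps_per_min * binned.bin_minutes
    hours_of_day = (
        binned.bin_start.hour.values
        + binned.bin_start.minute.values / 60.0
        + binned.bin_start.second.values / 3600.0
    )
    entries = track.entries
    for i in range(len(entries) - 1):
        prev = entries[i]
        nxt = next(
            (e for e in entries[i + 1 :]
             if lo <= (e.midpoint - prev.midpoint).total_seconds() / 3600.0 <= hi),
            None,
        )
        if nxt is None:
            log.debug("day after %s skipped: no flanking phase", prev.midpoint)
            continue
        mask = (binned.bin_start >= prev.midpoint) & (binned.bin_start < nxt.midpoint)
        rel = (hours_of_day[mask] - prev.phase_h) % 24.0
        h_bin = np.minimum(rel.astype(int), N_BINS - 1)
        xs = np.bincount(h_bin, weights=step_totals[mask], minlength=N_BINS)
        y = float(wrap_half_day(prev.phase_h - nxt.phase_h))
        for h in range(N_BINS):
            points.x[h].append(xs[h])
        ys.append(y)
        totals.append(xs.sum())
    points.y = np.array(ys)
    points.day_totals = np.array(totals)
    return points


def collect_prc_points(track: PhaseTrack, binned: BinnedSeries) -> PRCPointSet:
    """Relative-hour activity totals and nightly phase shifts, day by day.

    Activity between consecutive sleep midpoints is attributed to relative
    hour wrap(clock hour − previous-night phase); the day's response is
    y = wrap(c_prev − c_next) so a minimum arriving earlier the next night
    (an advance) is positive.  Days missing either flanking phase estimate
    are skipped.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 nights of phase estimates")
    return _collect(track, binned, CONSECUTIVE_NIGHT_RANGE_H)


def shuffle_control(points: PRCPointSet, seed: int = 0) -> PRCPointSet:
    """Permute day responses across days: the activity→shift link vanishes."""
    rng = np.random.default_rng(seed)
    out = PRCPointSet(x=[list(col) for col in points.x])
    out.y = points.y[rng.permutation(points.n_days)]
    out.day_totals = points.day_totals.copy()
    return out


# ---------------------------------------------------------------------------
# per-bin regression
# ---------------------------------------------------------------------------

def fit_bin_slopes(points: PRCPointSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin OLS slope of phase shift on steps (with intercept).

    Returns (slopes, standard errors, n per bin), slopes in h/step; bins
    with < 3 points or degenerate x variance get NaN and are excluded from
    the curve fit.
    """
    slopes = np.full(N_BINS, np.nan)
    ses = np.full(N_BINS, np.nan)
    ns = np.zeros(N_BINS, dtype=int)
    y = points.y
    for h in range(N_BINS):
        x = np.asarray(points.x[h], dtype=float)
        ns[h] = x.size
        if x.size < 3 or np.ptp(x) == 0:
            continue
        xc = x - x.mean()
        sxx = np.dot(xc, xc)
        slope = np.dot(xc, y - y.mean()) / sxx
        resid = (y - y.mean()) - slope * xc
        dof = x.size - 2
        ses[h] = np.sqrt(np.dot(resid, resid) / dof / sxx) if dof > 0 else np.nan
        slopes[h] = slope
    return slopes, ses, ns


# ---------------------------------------------------------------------------
# asymmetric sinusoid
# ---------------------------------------------------------------------------

def asymmetric_wave(h: np.ndarray, phase: float, tau: float) -> np.ndarray:
    """Unit-amplitude 24-h periodic wave with unequal half-periods.

    The trough sits at relative hour ``phase``; the rising half lasts
    ``tau`` hours (trough to peak) and the falling half 24 − tau, each a
    scaled half-cosine, so tau = 12 recovers the plain cosine.
    """
    u = (np.asarray(h, dtype=float) - phase) % 24.0
    rising = u < tau
    out = np.empty_like(u)
    out[rising] = -np.cos(np.pi * u[rising] / tau)
    out[~rising] = np.cos(np.pi * (u[~rising] - tau) / (24.0 - tau))
    return out


def fit_asymmetric_sinusoid(slopes: np.ndarray, slope_se: np.ndarray | None = None,
                            n_restarts: int = 24, seed: int = 0) -> dict:
    """Nonlinear least-squares fit of offset + A·wave(h; phase, tau).

    When standard errors are given the fit is inverse-variance weighted, so
    sparsely populated bins (whose slopes are numerically huge but
    meaningless) cannot drag the curve.  Multi-start over phase/tau grids
    plus random restarts; tau is kept in (1, 23) by bounds; ties broken by
    lowest RSS then lowest tau.  Requires at least 8 non-missing slopes.
    """
    slopes = np.asarray(slopes, dtype=float)
    ok = np.isfinite(slopes)
    if ok.sum() < 8:
        raise ValueError(f"need >= 8 non-missing slopes, have {int(ok.sum())}")
    # a bin's slope measures the average response over [h, h+1): centre it
    h = (np.arange(N_BINS, dtype=float) + 0.5)[ok]
    s = slopes[ok]
    if slope_se is not None:
        se = np.asarray(slope_se, dtype=float)[ok]
        good = np.isfinite(se) & (se > 0)
        w = np.where(good, 1.0 / np.where(good, se, 1.0), np.nanmedian(se[good]) ** -1
                     if good.any() else 1.0)
        w = w / w.max()
    else:
        w = np.ones_like(s)
    rng = np.random.default_rng(seed)

    def resid(p):
        off, amp, phase, tau = p
        return w * (off + amp * asymmetric_wave(h, phase, tau) - s)

    s_mean = float(np.sum(w**2 * s) / np.sum(w**2))
    s_amp = max(float(np.ptp(s[w > 0.05 * w.max()])) / 2.0, 1e-12)
    starts = [(s_mean, s_amp, ph, tau)
              for ph in (0.0, 6.0, 12.0, 18.0) for tau in (8.0, 12.0, 16.0)]
    while len(starts) < n_restarts:
        starts.append((s_mean, s_amp * rng.uniform(0.3, 2.0),
                       rng.uniform(0, 24), rng.uniform(2, 22)))
    best = None
    lb = [-np.inf, 0.0, -1e-9, 1.0 + 1e-9]
    ub = [np.inf, np.inf, 24.0, 23.0 - 1e-9]
    for p0 in starts:
        p0 = np.clip(p0, [v if np.isfinite(v) else -1e12 for v in lb],
                     [v if np.isfinite(v) else 1e12 for v in ub])
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        rss = float(np.sum(sol.fun**2))
        key = (round(rss, 14), sol.x[3])
        if best is None or key < best[0]:
            best = (key, sol.x, rss)
    if best is None:
        raise RuntimeError("asymmetric-sinusoid fit failed from all restarts")
    (_, x, rss) = best
    rss_mean = float(np.sum((w * (s - s_mean)) ** 2))
    return {
        "offset": float(x[0]),
        "amplitude": float(x[1]),
        "phase": float(x[2] % 24.0),
        "trough_to_peak": float(x[3]),
        "rss": rss,
        "rss_mean_only": rss_mean,
    }


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def period_from_offset(fit: PRCFit, mean_daily_steps_profile: Optional[np.ndarray] = None) -> float:
    """Intrinsic period, 24 − δ₀ hours, from the curve's zero-activity drift.

    δ₀ (advance positive, h/day) is the nightly shift a zero-activity day
    would show — the pure zero-activity intercept of the day-level response.
    With day-level points available it is estimated by regressing each day's
    shift y_d on the curve-predicted activity effect p_d = Σ_h m(h)·x_{d,h}
    and taking the intercept (the regression coefficient absorbs any
    amplitude error of the fitted curve).  Without day-level data it falls
    back to δ₀ = ȳ − Σ_h m(h)·x̄_h on the mean steps profile.  With no
    activity and no drift δ₀ = 0 and the period is exactly 24 h; a
    free-running clock with period 24.2 h gives δ₀ = −0.2.
    """
    m = fit.curve(np.arange(N_BINS, dtype=float) + 0.5)
    if mean_daily_steps_profile is None and fit.points is not None \
            and fit.points.n_days >= 3:
        X = fit.points.x_matrix()
        y = fit.points.y
        if fit.points.n_days >= int(1.5 * N_BINS):
            # enough days: intercept of the day-level linear response model
            # y_d = delta0 + sum_h beta_h x_dh, the exact zero-activity drift
            Z = np.column_stack([np.ones(len(y)), X])
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            return 24.0 - float(coef[0])
        p = X @ m
        if np.ptp(p) > 1e-12:
            # short series: intercept with the curve as the activity predictor
            _, delta0 = np.polyfit(p, y, 1)
            return 24.0 - float(delta0)
        return 24.0 - float(np.mean(y) - np.mean(p))
    profile = fit.bin_mean_steps if mean_daily_steps_profile is None \
        else np.asarray(mean_daily_steps_profile, dtype=float)
    delta0 = fit.mean_shift_h - float(np.sum(m * profile))
    return 24.0 - delta0


def prc_characteristics(fit: PRCFit) -> tuple[float, float, float]:
    """(sinusoidality, amplitude, horizontal shift) of a fitted curve.

    sinusoidality = 1 − RSS(curve)/RSS(mean-only), clipped to [0, 1]: the
    fraction of slope variance the 4-parameter wave explains.  A zero-
    amplitude fit leaves the horizontal shift non-identifiable (NaN).
    """
    sin_q = 0.0 if fit.rss_mean_only == 0 else 1.0 - fit.rss / fit.rss_mean_only
    sin_q = float(np.clip(sin_q, 0.0, 1.0))
    shift = fit.phase if fit.amplitude > 0 else np.nan
    if fit.amplitude == 0:
        log.warning("zero-amplitude PRC: horizontal shift is non-identifiable")
    return sin_q, float(fit.amplitude), float(shift)


def fit_prc(points: PRCPointSet, seed: int = 0) -> PRCFit:
    """Full PRC estimate from a point set: slopes, curve, period, characteristics."""
    slopes, ses, ns = fit_bin_slopes(points)
    pars = fit_asymmetric_sinusoid(slopes, slope_se=ses, seed=seed)
    fit = PRCFit(
        slopes=slopes, slope_se=ses, n_points=ns,
        offset=pars["offset"], amplitude=pars["amplitude"], phase=pars["phase"],
        trough_to_peak=pars["trough_to_peak"], rss=pars["rss"],
        rss_mean_only=pars["rss_mean_only"],
        bin_mean_steps=points.bin_mean_steps(),
        mean_shift_h=float(np.mean(points.y)) if points.n_days else np.nan,
        points=points,
    )
    fit.intrinsic_period_h = period_from_offset(fit)
    fit.sinusoidality, _, fit.horizontal_shift = prc_characteristics(fit)
    return fit


def prc_robustness_nonoverlap(track: PhaseTrack, binned: BinnedSeries,
                              seed: int = 0) -> PRCFit:
    """48-h variant: responses are phase changes between nights two apart.

    The two phase estimates then share no underlying data; per-bin x is
    still the single day's relative-hour activity.  Compared against the
    24-h PRC as a robustness check (the two should be nearly identical).
    """
    if len(track) < 3:
        raise ValueError("need at least 3 nights for the non-overlap variant")
    points = _collect(track, binned, NONOVERLAP_NIGHT_RANGE_H)
    if points.n_days == 0:
        raise ValueError("no night pairs separated by ~48 h")
    return fit_prc(points, seed=seed)
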