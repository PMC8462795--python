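"""Report rendering: actograms with phase overlays and PRC plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .inference import PhaseTrack  # noqa: E402
from .preprocess import BinnedSeries  # noqa: E402
from .prc import PRCFit, N_BINS  # noqa: E402

__all__ = ["plot_actogram", "plot_prc"]


def plot_actogram(binned: BinnedSeries, track: PhaseTrack | None = None,
                  double_plot: bool = True, path=None):
    """Raster of daily activity (black bars), one civil day per row,
    optionally double-plotted to 48 h, with the estimated phase (red line)
    and its shaded 80% band overlaid at its clock hour on each row."""
    df = pd.DataFrame({"t": binned.bin_start, "steps": binned.steps_per_min})
    df["day"] = df["t"].dt.normalize()
    days = sorted(df["day"].unique())
    day_pos = {d: i for i, d in enumerate(days)}
    width_h = 48.0 if double_plot else 24.0

    fig, ax = plt.subplots(figsize=(10, max(2.5, 0.28 * len(days))))
    smax = max(df["steps"].max(), 1.0)
    for d, sub in df.groupby("day"):
        row = day_pos[d]
        hours = (sub["t"] - d).dt.total_seconds().values / 3600.0
        h = 0.9 * sub["steps"].values / smax
        ax.bar(hours, h, width=24 / 288, bottom=row, color="black", align="edge")
        if double_plot and row + 1 in day_pos.values():
            ax.bar(hours + 24.0, h, width=24 / 288, bottom=row + 1,
                   color="black", align="edge")
    if track is not None and len(track):
        ys, xs, lo, hi = [], [], [], []
        for e in track:
            row = day_pos.get(e.midpoint.normalize())
            if row is None:
                continue
            xs.append(e.phase_h)
            lo.append(e.ci80[0])
            hi.append(e.ci80[1])
            ys.append(row + 0.5)
        xs, lo, hi, ys = map(np.asarray, (xs, lo, hi, ys))
        ax.plot(xs, ys, color="crimson", lw=1.5, label="CRHR phase")
        ax.fill_betweenx(ys, lo, hi, color="crimson", alpha=0.25, label="80% band")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlim(0, width_h)
    ax.set_ylim(len(days), 0)
    ax.set_xlabel("clock hour")
    ax.set_ylabel("day")
    ax.set_xticks(np.arange(0, width_h + 1, 6))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_prc(fit: PRCFit, shuffled: PRCFit | None = None,
             double_plot: bool = True, path=None):
    """Bin slopes with standard-error bars and the fitted asymmetric
    sinusoid; optionally extended to 36 h by double-plotting the first 12
    bins, with a shuffled-activity control curve dashed."""
    h = np.arange(N_BINS, dtype=float)
    hh = np.linspace(0, 36 if double_plot else 24, 400)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.axhline(0.0, color="grey", lw=0.7)
    ax.errorbar(h + 0.5, fit.slopes, yerr=fit.slope_se, fmt="ko", ms=4, lw=1,
                label="bin slopes")
    if double_plot:
        ax.errorbar(h[:12] + 24.5, fit.slopes[:12], yerr=fit.slope_se[:12],
                    fmt="o", ms=4, lw=1, color="0.6")
    ax.plot(hh, fit.curve(hh - 0.5), color="crimson", lw=2, label="fitted curve")
    if shuffled is not None:
        ax.plot(hh, shuffled.curve(hh - 0.5), "k--", lw=1.2, label="shuffled control")
    ax.set_xlabel("hours after CRHR minimum")
    ax.set_ylabel("phase shift per step (h/step)")
    ax.set_title(f"PRC: period {fit.intrinsic_period_h:.2f} h, "
                 f"sinusoidality {fit.sinusoidality:.2f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
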