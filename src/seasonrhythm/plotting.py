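"""Double plots: two concatenated annual cycles with bin means and the fitted cosine."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 - headless environments

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .timeangles import PERIOD_DAYS, TWO_PI, date_to_angle


def double_plot(dates, values, fit=None, *, period_days: float = PERIOD_DAYS,
                bin_months: int = 2, ax=None, ylabel: str = "outcome"):
    """Two concatenated annual cycles: bin means +/- SEM and the fitted curve.

    `fit` may be a SeasonalFit; its cosine component is drawn around the
    sample mean of `values`.
    """
    theta = np.atleast_1d(date_to_angle(np.asarray(dates), period_days))
    day = theta / TWO_PI * period_days
    values = np.asarray(values, dtype=float)

    n_bins = int(round(12 / bin_months))
    edges = np.linspace(0, period_days, n_bins + 1)
    which = np.clip(np.digitize(day, edges) - 1, 0, n_bins - 1)
    centers, means, sems = [], [], []
    for b in range(n_bins):
        sel = values[which == b]
        if len(sel) == 0:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        means.append(sel.mean())
        sems.append(sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else 0.0)
    centers, means, sems = map(np.asarray, (centers, means, sems))

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    for cycle in (0, 1):
        off = cycle * period_days
        ax.errorbar(centers + off, means, yerr=sems, fmt="o", color="k",
                    capsize=3, markersize=4)
    if fit is not None:
        grid = np.linspace(0, 2 * period_days, 400)
        curve = (values.mean()
                 + fit.amplitude * np.cos(TWO_PI * grid / period_days
                                          - fit.acrophase_rad))
        ax.plot(grid, curve, "b:", lw=1.5)
    ax.set_xlim(0, 2 * period_days)
    month_starts = np.array([0, 59, 120, 181, 243, 304])
    labels = ["Jan", "Mar", "May", "Jul", "Sep", "Nov"]
    ticks = np.concatenate([month_starts, month_starts + period_days])
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels * 2, fontsize=8)
    ax.set_xlabel("date (double plotted)")
    ax.set_ylabel(ylabel)
    return ax


def save_double_plot(dates, values, fit, path, **kwargs):
    ax = double_plot(dates, values, fit, **kwargs)
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
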