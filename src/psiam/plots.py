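"""Plotting helpers for the standard diagnostic panels.

Thin matplotlib wrappers over the metric tables: RT distributions with
the model components overlaid, tachometric curves per strength,
time-delay curves, response-class shares vs RT, and the within-session
fast-response fraction.  Each helper draws on a provided (or fresh)
axes object and returns it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .densities import DensityGrid
from .metrics import fast_response_fraction, tachometric_curve, time_delay_curve

__all__ = [
    "plot_rt_distribution",
    "plot_tachometric",
    "plot_time_delay",
    "plot_class_shares",
    "plot_fast_fraction",
]


def _axes(ax=None):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_rt_distribution(
    outcomes: pd.DataFrame,
    components: dict[str, DensityGrid] | None = None,
    bin_ms: float = 10.0,
    ax=None,
):
    """Histogram of withdrawal times with model densities overlaid."""
    ax = _axes(ax)
    rt = outcomes["rt_s"].to_numpy(dtype=float)
    rt = rt[np.isfinite(rt) & (rt > -0.3) & (rt <= 1.0)]
    ax.hist(rt, bins=np.arange(-0.3, 1.0, bin_ms / 1000.0), density=True,
            color="0.8", label="data")
    for label, grid in (components or {}).items():
        ax.plot(grid.times, grid.pdf, label=label)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("density (1/s)")
    ax.legend(frameon=False)
    return ax


def plot_tachometric(outcomes: pd.DataFrame, bin_ms: float = 10.0, ax=None):
    """Accuracy vs RT, one line per absolute stimulus strength."""
    ax = _axes(ax)
    curve = tachometric_curve(outcomes, bin_ms=bin_ms, by_strength=True)
    for s, grp in curve[~curve["low_n"]].groupby("strength"):
        ax.plot(grp["rt_bin_s"], grp["accuracy"], label=f"|s| = {s:g}")
        ax.fill_between(grp["rt_bin_s"], grp["ci_lo"], grp["ci_hi"], alpha=0.2)
    ax.axhline(0.5, ls=":", c="k", lw=0.8)
    ax.set_xlabel("reaction time (s)")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0.3, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_time_delay(
    outcomes: pd.DataFrame,
    reference_strength: float = 0.0,
    grid=None,
    ax=None,
):
    """Time-delay curves of each strength against the reference strength."""
    ax = _axes(ax)
    grid = np.arange(0.0, 0.7, 0.001) if grid is None else np.asarray(grid)
    rt = outcomes["rt_s"].to_numpy(dtype=float)
    s = np.abs(outcomes["strength_signed"].to_numpy(dtype=float))
    ok = np.isfinite(rt) & (rt > -0.3) & (rt <= 1.0)
    ref = rt[ok & (s == reference_strength)]
    for sv in sorted(set(np.round(s[ok], 9)) - {reference_strength}):
        curve = time_delay_curve(rt[ok & (s == sv)], ref, grid)
        ax.plot(curve["time_s"], 1000 * curve["delay_s"], label=f"|s| = {sv:g}")
    ax.axhline(0.0, ls=":", c="k", lw=0.8)
    ax.set_xlabel("reaction time (s)")
    ax.set_ylabel("time delay (ms)")
    ax.legend(frameon=False)
    return ax


def plot_class_shares(outcomes: pd.DataFrame, bin_ms: float = 25.0, ax=None):
    """Share of proactive / reactive / contaminant responses per RT bin."""
    ax = _axes(ax)
    rt = outcomes["rt_s"].to_numpy(dtype=float)
    ok = np.isfinite(rt) & (rt <= 1.0) & outcomes["class"].isin(
        ["proactive", "reactive", "contaminant", "FB"]
    ).to_numpy()
    width = bin_ms / 1000.0
    bins = np.floor(rt[ok] / width).astype(int)
    cls = outcomes.loc[ok, "class"].replace({"FB": "proactive"})
    tab = pd.crosstab(bins, cls, normalize="index")
    centers = (tab.index.to_numpy() + 0.5) * width
    for name, color in [("proactive", "tab:red"), ("reactive", "tab:green"),
                        ("contaminant", "k")]:
        if name in tab:
            ax.plot(centers, tab[name], color=color, label=name)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("share of responses")
    ax.legend(frameon=False)
    return ax


def plot_fast_fraction(outcomes: pd.DataFrame, block: int = 50, ax=None):
    """Fraction of fast withdrawals per trial block, one line per reward size."""
    ax = _axes(ax)
    if outcomes["reward_size_ul"].notna().any():
        for r, grp in outcomes.groupby("reward_size_ul"):
            frac = fast_response_fraction(grp, block=block)
            ax.plot(frac["block_start"], frac["fraction_fast"], label=f"{r:g} uL")
        ax.legend(frameon=False)
    else:
        frac = fast_response_fraction(outcomes, block=block)
        ax.plot(frac["block_start"], frac["fraction_fast"])
    ax.set_xlabel("trial within session")
    ax.set_ylabel("fraction fast (< 50 ms or FB)")
    return ax
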