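"""Descriptive statistics over outcome tables.

* tachometric curves: choice accuracy in small RT bins;
* time-delay curves: quantile-matched horizontal distance between two RT
  cumulative distributions;
* RT-evidence modulation onset: earliest truncation time at which the
  strongest- and weakest-stimulus RT distributions differ by a one-sided
  Kolmogorov-Smirnov test;
* fast-response fraction: share of withdrawals faster than 50 ms after
  stimulus onset (fixation breaks included) per within-session block.

Fixation breaks carry no scored choice, so they are excluded from the
tachometric and time-delay computations but counted as fast withdrawals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .params import T_CENSOR

__all__ = [
    "tachometric_curve",
    "time_delay_curve",
    "delay_between_cdfs",
    "modulation_onset",
    "fast_response_fraction",
]


def _choice_bearing(outcomes: pd.DataFrame) -> pd.DataFrame:
    rt = outcomes["rt_s"].to_numpy(dtype=float)
    ok = (
        np.isfinite(rt)
        & (rt > 0)
        & (rt <= T_CENSOR)
        & (outcomes["choice"].isin(["left", "right"]).to_numpy())
        & (outcomes["class"].isin(["proactive", "reactive", "contaminant"]).to_numpy()
           if "class" in outcomes else True)
        & outcomes["correct"].notna().to_numpy()
    )
    return outcomes.loc[ok]


def tachometric_curve(
    outcomes: pd.DataFrame,
    bin_ms: float = 10.0,
    by_strength: bool = False,
    min_n: int = 10,
) -> pd.DataFrame:
    """Accuracy of valid, choice-bearing responses per RT bin.

    Returns one row per bin (optionally per absolute stimulus strength)
    with the bin center, accuracy, trial count, a normal-approximation
    binomial CI, and a low-count flag.
    """
    data = _choice_bearing(outcomes)
    width = bin_ms / 1000.0
    rt = data["rt_s"].to_numpy(dtype=float)
    corr = data["correct"].to_numpy(dtype=float)
    strength = np.abs(data["strength_signed"].to_numpy(dtype=float))
    bins = np.floor(rt / width).astype(int)

    frame = pd.DataFrame({"bin": bins, "correct": corr, "strength": strength})
    keys = ["strength", "bin"] if by_strength else ["bin"]
    g = frame.groupby(keys)["correct"].agg(["mean", "count"]).reset_index()
    g["rt_bin_s"] = (g["bin"] + 0.5) * width
    se = np.sqrt(np.maximum(g["mean"] * (1 - g["mean"]), 0) / g["count"])
    g["ci_lo"] = g["mean"] - 1.96 * se
    g["ci_hi"] = g["mean"] + 1.96 * se
    g["low_n"] = g["count"] < min_n
    g = g.rename(columns={"mean": "accuracy", "count": "n"})
    cols = (["strength"] if by_strength else []) + [
        "rt_bin_s", "accuracy", "n", "ci_lo", "ci_hi", "low_n"
    ]
    return g[cols]


def time_delay_curve(sample, reference, grid) -> pd.DataFrame:
    """Horizontal distance between two empirical RT cdfs.

    At each grid time ``T`` the delay is ``T_r - T`` where the reference
    cdf at ``T_r`` matches the sample cdf at ``T``.  Both cdfs use linear
    interpolation between their jump points, so the curve of a sample
    against itself is identically zero.  Positive values mean the sample
    is faster than the reference at that quantile.  NA where the sample
    quantile falls outside the reference cdf's range.
    """
    sample = np.sort(np.asarray(sample, dtype=float))
    reference = np.sort(np.asarray(reference, dtype=float))
    grid = np.asarray(grid, dtype=float)
    q_s = np.arange(1, sample.size + 1) / sample.size
    q = np.interp(grid, sample, q_s, left=0.0, right=1.0)
    q_ref = np.arange(1, reference.size + 1) / reference.size
    t_r = np.interp(q, q_ref, reference, left=np.nan, right=np.nan)
    t_r[(q <= q_ref[0]) | (grid < sample[0]) | (grid > sample[-1])] = np.nan
    return pd.DataFrame({"time_s": grid, "delay_s": t_r - grid})


def delay_between_cdfs(times, cdf, cdf_ref) -> pd.DataFrame:
    """Time-delay curve between two tabulated (analytic) cdfs."""
    times = np.asarray(times, dtype=float)
    cdf = np.asarray(cdf, dtype=float)
    cdf_ref = np.asarray(cdf_ref, dtype=float)
    # invert the reference cdf at the sample's level, inside its range only
    lo, hi = cdf_ref.min(), cdf_ref.max()
    t_r = np.interp(cdf, cdf_ref, times, left=np.nan, right=np.nan)
    t_r[(cdf < lo) | (cdf > hi) | (cdf <= 0)] = np.nan
    return pd.DataFrame({"time_s": times, "delay_s": t_r - times})


def modulation_onset(
    rts_strong,
    rts_weak,
    alpha: float = 0.05,
    step_ms: float = 1.0,
    t_max: float = T_CENSOR,
    min_n: int = 20,
    exact_below: int = 50,
) -> float | None:
    """Earliest time at which stimulus strength measurably speeds RTs.

    For each candidate ``t``, both RT samples are truncated to ``rt <= t``
    and compared by a one-sided two-sample KS test with the alternative
    that the strong-stimulus cdf lies above the weak one (stronger
    stimuli faster).  The onset is the time at which the comparison
    becomes significant *and stays significant* through the end of the
    scan (the start of the trailing run of significant tests); a
    momentary dip below ``alpha`` that later recovers does not count.
    Anchoring on the final test keeps the null detection rate at ``alpha``
    despite the nested multiple comparisons.  Returns None when even the
    full samples do not differ.
    """
    strong = np.sort(np.asarray(rts_strong, dtype=float))
    weak = np.sort(np.asarray(rts_weak, dtype=float))
    step = step_ms / 1000.0
    start = max(strong[0] if strong.size else 0.0, weak[0] if weak.size else 0.0)
    ts = np.arange(max(step, np.ceil(start / step) * step), t_max + step / 2, step)
    onset = None
    for t in ts:
        s = strong[: np.searchsorted(strong, t, side="right")]
        w = weak[: np.searchsorted(weak, t, side="right")]
        if s.size < min_n or w.size < min_n:
            continue
        method = "exact" if min(s.size, w.size) < exact_below else "asymp"
        res = stats.ks_2samp(s, w, alternative="greater", method=method)
        if res.pvalue < alpha:
            if onset is None:
                onset = float(t)
        else:
            onset = None
    return onset


def fast_response_fraction(
    outcomes: pd.DataFrame,
    threshold_s: float = 0.05,
    block: int = 50,
) -> pd.DataFrame:
    """Fraction of fast withdrawals (RT < threshold after stimulus onset,
    or any fixation break) per block of trial positions within session."""
    rt = outcomes["rt_s"].to_numpy(dtype=float)
    is_fb = (outcomes["class"] == "FB").to_numpy() if "class" in outcomes else rt < 0
    fast = is_fb | (rt < threshold_s)
    blk = ((outcomes["trial_index"].to_numpy(dtype=float) - 1) // block).astype(int)
    frame = pd.DataFrame({"block": blk, "fast": fast.astype(float)})
    g = frame.groupby("block")["fast"].agg(["mean", "count"]).reset_index()
    g["block_start"] = g["block"] * block + 1
    return g.rename(columns={"mean": "fraction_fast", "count": "n"})[
        ["block", "block_start", "fraction_fast", "n"]
    ]
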