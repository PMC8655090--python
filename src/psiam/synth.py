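"""Synthetic subjects and sessions with the task's trial structure.

Sessions emulate a rat reaction-time two-alternative task: a 300 ms
fixation period, stimulus strengths drawn from a configurable set with a
random rewarded side, optional catch trials (10% silent, or 5% + 5%
advanced/delayed onsets at full strength), reward-size session types
(12/24/48 uL), and an optional blockwise expectation-bias sign.

Subjects are drawn uniformly within the central portion of each MLE
search bound, so every generated parameter vector is fittable by
construction; the closed loop generate -> simulate -> fit is the
package's primary end-to-end test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import FIT_BOUNDS, RatParams, T_FIX

__all__ = ["generate_rat", "generate_sessions", "REWARD_WEIGHT_RANGES"]

#: Draw ranges for the reward-model drift weights.  Signs of the defaults
#: follow the behavioral findings: bigger rewards speed the action-
#: initiation process (w_r > 0) while fatigue (trial count, w_t < 0) and
#: satiety (consumed reward, w_c < 0) slow it.
REWARD_WEIGHT_RANGES: dict[str, tuple[float, float]] = {
    "w_0": (3.0, 6.5),
    "w_r": (0.02, 0.05),  # 1/(s uL)
    "w_t": (-0.006, -0.002),  # 1/(s trial)
    "w_c": (-1.2e-4, -4e-5),  # 1/(s uL consumed)
}


def _central(lo: float, hi: float, central: float, rng) -> float:
    pad = 0.5 * (1.0 - central) * (hi - lo)
    return float(rng.uniform(lo + pad, hi - pad))


def _behavioral_profile(rat: RatParams, strengths) -> tuple[float, float]:
    """Analytic (proactive share, FB fraction) of a subject at mid-session.

    Share of the observed-response mass inside the analysis window that
    the AI branch contributes, averaged over the strength set, and the
    probability of a fixation break (AI bound hit before stimulus onset).
    """
    from .densities import ai_cdf, ai_pdf, default_grid, ea_total_pdf_cdf
    from .params import AIParams

    k_mid = 350
    ai = AIParams(rat.nu_a0 + rat.nu_trial * k_mid, rat.theta_a, rat.t_a)
    t = default_grid()
    p_a = ai_pdf(t, ai)
    c_a = ai_cdf(t, ai)
    pro = rea = 0.0
    for s in strengths:
        p_e, c_e = ea_total_pdf_cdf(t - rat.t_e, rat.nu_e * s, rat.theta_e, rat.z_e)
        pro += np.trapezoid(p_a * (1 - c_e), t)
        rea += np.trapezoid(p_e * (1 - c_a), t)
    fb = float(ai_cdf(np.array([0.0]), ai)[0])
    return pro / max(pro + rea, 1e-12), fb


def generate_rat(
    rng=None,
    mode: str = "standard",
    central: float = 0.6,
    strengths: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0),
    max_draws: int = 100_000,
    **overrides,
) -> RatParams:
    """Draw a synthetic subject uniformly inside the central fraction of
    each fitting bound; keyword overrides pin individual parameters.

    Draws are resampled until the subject exhibits the task's behavioral
    regime -- a proactive share between 15% and 85% of responses and a
    fixation-break probability between 4% and 35%, bracketing the
    observed ~16% FBs and ~35% express responses -- so that both race
    processes are expressed in (and recoverable from) the data.  A
    parameter box in which one process never wins describes a different
    behavioral phenotype than the one being modeled.  The AI latency is
    additionally kept above ``-T_fix``: the process starts ramping at
    fixation onset after nonnegative afferent and motor delays, so more
    negative values have no physical reading (the wider MLE search bound
    is just a safety margin).
    """
    rng = np.random.default_rng(rng)
    names = ["nu_a0", "nu_trial", "theta_a", "t_a", "nu_e", "theta_e", "t_e", "c", "d", "beta"]
    for _ in range(max_draws):
        vals = {n: _central(*FIT_BOUNDS[n], central, rng) for n in names}
        # the AI starts at fixation onset plus nonnegative latencies, so the
        # physically meaningful latency range is clipped at -T_fix
        lo_ta, hi_ta = FIT_BOUNDS["t_a"]
        pad = 0.5 * (1.0 - central) * (hi_ta - lo_ta)
        vals["t_a"] = float(rng.uniform(max(lo_ta + pad, -T_FIX + 0.02), hi_ta - pad))
        vals["z_e"] = 0.0
        if mode == "biased":
            vals["z_e"] = _central(*FIT_BOUNDS["z_e"], central, rng)
            # keep the offset strictly inside the bounds
            vals["z_e"] = float(
                np.clip(vals["z_e"], -0.95 * vals["theta_e"], 0.95 * vals["theta_e"])
            )
        if mode == "reward":
            for w, (lo, hi) in REWARD_WEIGHT_RANGES.items():
                vals[w] = float(rng.uniform(lo, hi))
            vals["nu_trial"] = 0.0
        vals.update(overrides)
        rat = RatParams(**vals)
        probe = rat if mode != "reward" else rat.replace(
            nu_a0=rat.w_0 + rat.w_r * 24.0, nu_trial=0.0
        )
        v_end = (probe.nu_a0 + probe.nu_trial * 700) if mode != "reward" else 1.0
        if v_end <= 0:
            continue
        # cheap closed-form FB screen before the full density probe
        from .densities import ai_cdf
        from .params import AIParams

        ai = AIParams(probe.nu_a0 + probe.nu_trial * 350, probe.theta_a, probe.t_a)
        fb = float(ai_cdf(np.array([0.0]), ai)[0])
        if not (0.04 <= fb <= 0.35):
            continue
        share, _ = _behavioral_profile(probe, strengths)
        if 0.15 <= share <= 0.85:
            return rat
    raise RuntimeError("could not draw a subject in the behavioral regime")


def generate_sessions(
    rng=None,
    n_sessions: int = 1,
    n_trials: int = 700,
    strengths: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0),
    catch: str = "none",  # none | silent | shift
    silent_frac: float = 0.10,
    advanced_frac: float = 0.05,
    delayed_frac: float = 0.05,
    delta_advanced: float = -0.15,
    delta_delayed: float = +0.15,
    reward_sizes: tuple[float, ...] = (24.0,),
    bias: bool = False,
    block_len: int = 80,
    first_session: int = 0,
) -> pd.DataFrame:
    """Emit a trial table for ``n_sessions`` sessions.

    Shifted catch trials always run at full strength; silent trials keep
    their scheduled strength for bookkeeping but the stimulus never
    plays.  ``target_side`` records the rewarded side even when the
    strength is 0 (predetermined category sequence).
    """
    rng = np.random.default_rng(rng)
    if catch == "silent" and silent_frac > 1:
        raise ValueError("catch fractions must sum to at most 1")
    if catch == "shift" and advanced_frac + delayed_frac > 1:
        raise ValueError("catch fractions must sum to at most 1")
    frames = []
    for s_i in range(first_session, first_session + n_sessions):
        k = np.arange(1, n_trials + 1)
        strength = rng.choice(strengths, size=n_trials)
        side = rng.choice([-1.0, 1.0], size=n_trials)
        signed = strength * side
        target = np.where(strength > 0, side, rng.choice([-1.0, 1.0], size=n_trials))
        silent = np.zeros(n_trials, dtype=bool)
        delta = np.zeros(n_trials)
        if catch == "silent":
            silent = rng.random(n_trials) < silent_frac
        elif catch == "shift":
            u = rng.random(n_trials)
            adv = u < advanced_frac
            dly = (u >= advanced_frac) & (u < advanced_frac + delayed_frac)
            delta[adv] = delta_advanced
            delta[dly] = delta_delayed
            # shifted catch trials run at maximum strength
            signed[adv | dly] = side[adv | dly]
            target[adv | dly] = side[adv | dly]
        b_k = np.zeros(n_trials, dtype=int)
        if bias:
            # two-state block alternation of the expected side
            blocks = (k - 1) // block_len
            b_k = np.where(blocks % 2 == 0, 1, -1)
        frames.append(
            pd.DataFrame(
                {
                    "session": s_i,
                    "trial_index": k,
                    "strength_signed": signed,
                    "bias_sign": b_k,
                    "reward_size_ul": float(rng.choice(reward_sizes)),
                    "consumed_ul": 0.0,
                    "onset_shift_s": delta,
                    "silent": silent,
                    "target_side": target,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
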