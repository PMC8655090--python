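"""Stochastic trial-level simulation of the AI/EA race.

Euler-Maruyama with a default 0.1 ms time step and sticky absorbing
bounds.  The simulator is the Monte-Carlo oracle for the analytic
densities and the engine for choice predictions: when the AI process
wins (proactive response) the EA keeps integrating the stimulus evidence
already heard -- the stimulus stops at withdrawal, so the total
stimulus-driven integration time equals the withdrawal time since
stimulus onset -- and the choice is the sign of the final EA state.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .params import AIParams, ContaminantParams, EAParams, RatParams, T_CENSOR, T_FIX
from .trials import ai_drift_vector, normalize_trials

__all__ = [
    "simulate_trial",
    "simulate_dataset",
    "simulate_fpt_ai",
    "simulate_fpt_ea",
    "sample_contaminant_rt",
]

_WIN_PROACTIVE = 0
_WIN_REACTIVE = 1
_WIN_NONE = 2


@njit(cache=True)
def _race_kernel(seed, dt, horizon, v_a, theta_a, t_a, has_ea, v_e, theta_e, z_e, t_e, delta):
    """Race simulation for n trials; returns (rt, winner, x_final, ea_hit)."""
    np.random.seed(seed)
    n = v_a.shape[0]
    rt = np.empty(n)
    winner = np.empty(n, dtype=np.int8)
    x_final = np.empty(n)
    sdt = math.sqrt(dt)
    for i in range(n):
        # --- AI: single bound from 0, diffusing from absolute time t_a
        T_A = np.inf
        y = 0.0
        max_a = int((horizon - t_a[i]) / dt)
        for s in range(1, max_a + 1):
            y_prev = y
            y += v_a[i] * dt + sdt * np.random.normal()
            if y >= theta_a[i]:
                T_A = t_a[i] + s * dt
                break
            # Brownian-bridge within-step crossing (removes the O(sqrt(dt))
            # first-passage bias of plain end-point detection)
            g = (theta_a[i] - y_prev) * (theta_a[i] - y)
            if g < 10.0 * dt and np.random.random() < math.exp(-2.0 * g / dt):
                T_A = t_a[i] + s * dt
                break
        # --- EA: two sticky bounds from z_e, stimulus onset at delta
        T_E = np.inf
        x = z_e[i]
        if has_ea[i]:
            if np.isfinite(T_A):
                u_stop = T_A - delta[i]  # heard-stimulus duration if AI wins
            else:
                u_stop = horizon - delta[i] - t_e[i]
            max_e = int(u_stop / dt)
            for s in range(1, max_e + 1):
                x_prev = x
                x += v_e[i] * dt + sdt * np.random.normal()
                if x >= theta_e[i]:
                    x = theta_e[i]
                    T_E = delta[i] + t_e[i] + s * dt
                    break
                if x <= -theta_e[i]:
                    x = -theta_e[i]
                    T_E = delta[i] + t_e[i] + s * dt
                    break
                g_up = (theta_e[i] - x_prev) * (theta_e[i] - x)
                if g_up < 10.0 * dt and np.random.random() < math.exp(-2.0 * g_up / dt):
                    x = theta_e[i]
                    T_E = delta[i] + t_e[i] + s * dt
                    break
                g_lo = (theta_e[i] + x_prev) * (theta_e[i] + x)
                if g_lo < 10.0 * dt and np.random.random() < math.exp(-2.0 * g_lo / dt):
                    x = -theta_e[i]
                    T_E = delta[i] + t_e[i] + s * dt
                    break
        if T_E < T_A:
            rt[i] = T_E
            winner[i] = 1
        elif T_A < T_E:
            rt[i] = T_A
            winner[i] = 0
        elif np.isfinite(T_A):  # same-step tie: fair coin
            rt[i] = T_A
            winner[i] = 0 if np.random.random() < 0.5 else 1
        else:
            rt[i] = np.nan
            winner[i] = 2
        x_final[i] = x
    return rt, winner, x_final


@njit(cache=True)
def _fpt_single_bound(seed, dt, v, theta, n, horizon):
    np.random.seed(seed)
    out = np.empty(n)
    sdt = math.sqrt(dt)
    max_s = int(horizon / dt)
    for i in range(n):
        y = 0.0
        out[i] = np.nan
        for s in range(1, max_s + 1):
            y_prev = y
            y += v * dt + sdt * np.random.normal()
            if y >= theta:
                out[i] = s * dt
                break
            g = (theta - y_prev) * (theta - y)
            if g < 10.0 * dt and np.random.random() < math.exp(-2.0 * g / dt):
                out[i] = s * dt
                break
    return out


@njit(cache=True)
def _fpt_two_bound(seed, dt, v, theta, z, n, horizon):
    np.random.seed(seed)
    rts = np.empty(n)
    side = np.zeros(n, dtype=np.int8)
    sdt = math.sqrt(dt)
    max_s = int(horizon / dt)
    for i in range(n):
        x = z
        rts[i] = np.nan
        for s in range(1, max_s + 1):
            x_prev = x
            x += v * dt + sdt * np.random.normal()
            if x >= theta:
                rts[i] = s * dt
                side[i] = 1
                break
            if x <= -theta:
                rts[i] = s * dt
                side[i] = -1
                break
            g_up = (theta - x_prev) * (theta - x)
            if g_up < 10.0 * dt and np.random.random() < math.exp(-2.0 * g_up / dt):
                rts[i] = s * dt
                side[i] = 1
                break
            g_lo = (theta + x_prev) * (theta + x)
            if g_lo < 10.0 * dt and np.random.random() < math.exp(-2.0 * g_lo / dt):
                rts[i] = s * dt
                side[i] = -1
                break
    return rts, side


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_fpt_ai(params: AIParams, n: int, dt: float = 1e-4, rng=None, horizon: float = 5.0):
    """First-passage times of the AI process alone (relative to stimulus
    onset, i.e. including ``t_a``); NaN where the bound was not reached."""
    rng = np.random.default_rng(rng)
    fpt = _fpt_single_bound(_seed_from(rng), dt, params.v_a, params.theta_a, n, horizon)
    return fpt + params.t_a


def simulate_fpt_ea(params: EAParams, n: int, dt: float = 1e-4, rng=None, horizon: float = 5.0):
    """EA exit times (including ``t_e``) and exit side (+1 upper / -1 lower)."""
    rng = np.random.default_rng(rng)
    rts, side = _fpt_two_bound(
        _seed_from(rng), dt, params.v_e, params.theta_e, params.z_e, n, horizon
    )
    return rts + params.t_e, side


def sample_contaminant_rt(cont: ContaminantParams, n: int, rng=None) -> np.ndarray:
    """Inverse-cdf sampling from the exponential+uniform contaminant."""
    rng = np.random.default_rng(rng)
    span = cont.t_hi - cont.t_lo
    from_exp = rng.random(n) < cont.d
    u = rng.random(n)
    out = np.empty(n)
    if cont.beta * span < 1e-9:
        out[from_exp] = cont.t_lo + span * u[from_exp]
    else:
        norm = -np.expm1(-cont.beta * span)
        out[from_exp] = cont.t_lo - np.log1p(-u[from_exp] * norm) / cont.beta
    out[~from_exp] = cont.t_lo + span * u[~from_exp]
    return out


def simulate_trial(
    ai: AIParams,
    ea: EAParams | None,
    cont: ContaminantParams | None = None,
    dt: float = 1e-4,
    rng=None,
    horizon: float = 5.0,
) -> dict:
    """Simulate a single trial; returns a dict with rt_s, choice, class."""
    if dt <= 0 or dt > 1e-3:
        raise ValueError("dt must be positive and <= 1 ms")
    rng = np.random.default_rng(rng)
    cont = cont or ContaminantParams(c=0.0)
    df = pd.DataFrame({"trial_index": [1], "strength_signed": [0.0]})
    df = normalize_trials(df)
    rat_like = RatParams(
        nu_a0=ai.v_a, nu_trial=0.0, theta_a=ai.theta_a, t_a=ai.t_a,
        nu_e=ea.v_e if ea is not None else 0.0,
        theta_e=ea.theta_e if ea is not None else 1.0,
        t_e=ea.t_e if ea is not None else 0.05,
        z_e=0.0, c=cont.c, d=cont.d, beta=cont.beta,
    )
    df["silent"] = ea is None
    if ea is not None and ea.z_e != 0.0:
        df["bias_sign"] = 1
        rat_like = rat_like.replace(z_e=ea.z_e)
        df["strength_signed"] = ea.v_e / rat_like.nu_e if rat_like.nu_e else 0.0
    out = simulate_dataset(rat_like, df, dt=dt, rng=rng, horizon=horizon)
    return out.iloc[0].to_dict()


def simulate_dataset(
    rat: RatParams,
    trials: pd.DataFrame,
    dt: float = 1e-4,
    rng=None,
    mode: str = "standard",
    horizon: float = 5.0,
) -> pd.DataFrame:
    """Simulate outcomes for a whole trial table.

    Returns the table with added columns ``rt_s``, ``choice``
    (left/right/none), ``class`` (proactive/reactive/contaminant/FB/
    invalid) and ``correct``.  In reward mode the consumed-reward
    covariate is accumulated from the simulated outcomes session by
    session, so trials are simulated sequentially.
    """
    if dt <= 0 or dt > 1e-3:
        raise ValueError("dt must be positive and <= 1 ms")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rng = np.random.default_rng(rng)
    trials = normalize_trials(trials)

    if mode == "reward":
        return _simulate_reward_mode(rat, trials, dt, rng, horizon)

    v_a = ai_drift_vector(rat, trials, mode)
    return _simulate_block(rat, trials, v_a, dt, rng, horizon)


def _simulate_block(rat, trials, v_a, dt, rng, horizon) -> pd.DataFrame:
    n = len(trials)
    s = trials["strength_signed"].to_numpy(dtype=float)
    silent = trials["silent"].to_numpy(dtype=bool)
    bias = trials["bias_sign"].to_numpy(dtype=float)
    delta = trials["onset_shift_s"].to_numpy(dtype=float)

    cont = rat.contaminant()
    is_cont = rng.random(n) < cont.c

    rt = np.full(n, np.nan)
    winner = np.full(n, _WIN_NONE, dtype=np.int8)
    x_final = np.full(n, 0.0)

    idx = np.flatnonzero(~is_cont)
    if idx.size:
        r, w, x = _race_kernel(
            _seed_from(rng), dt, horizon,
            np.ascontiguousarray(v_a[idx]),
            np.full(idx.size, rat.theta_a),
            np.full(idx.size, rat.t_a),
            np.ascontiguousarray(~silent[idx]),
            np.ascontiguousarray(rat.nu_e * s[idx]),
            np.full(idx.size, rat.theta_e),
            np.ascontiguousarray(rat.z_e * bias[idx]),
            np.full(idx.size, rat.t_e),
            np.ascontiguousarray(delta[idx]),
        )
        rt[idx] = r
        winner[idx] = w
        x_final[idx] = x

    cidx = np.flatnonzero(is_cont)
    if cidx.size:
        rt[cidx] = sample_contaminant_rt(cont, cidx.size, rng)

    return _assemble(trials, rt, winner, x_final, is_cont, silent, bias, rat, rng)


def _assemble(trials, rt, winner, x_final, is_cont, silent, bias, rat, rng):
    n = len(trials)
    delta = trials["onset_shift_s"].to_numpy(dtype=float)
    s = trials["strength_signed"].to_numpy(dtype=float)

    # choice: reactive -> bound hit (x_final is at +/- theta); proactive ->
    # sign of final EA state (expectation sign if nothing was heard);
    # contaminant -> fair coin
    coin = rng.random(n) < 0.5
    choice_sign = np.where(x_final > 0, 1, np.where(x_final < 0, -1, np.where(coin, 1, -1)))
    choice_sign = np.where(is_cont, np.where(rng.random(n) < 0.5, 1, -1), choice_sign)

    cls = np.full(n, "proactive", dtype=object)
    cls[winner == _WIN_REACTIVE] = "reactive"
    cls[winner == _WIN_NONE] = "invalid"
    cls[is_cont] = "contaminant"
    # fixation ends at the stimulus onset for advanced trials, at the
    # scheduled onset otherwise; withdrawals before that are FBs
    fb_cut = np.where(silent, 0.0, np.minimum(0.0, delta))
    is_fb = rt < fb_cut
    cls[is_fb & ~is_cont & (winner != _WIN_NONE)] = "FB"
    cls[(rt > T_CENSOR) & (cls != "invalid")] = "invalid"
    # a latent bound hit before fixation onset is unobservable
    cls[rt <= -T_FIX] = "invalid"

    target = np.where(
        np.abs(s) > 0,
        np.sign(s),
        trials["target_side"].to_numpy(dtype=float) if "target_side" in trials else np.nan,
    )
    correct = np.where(np.isnan(target), np.nan, (choice_sign == target).astype(float))
    correct = np.where(is_fb | (cls == "invalid"), np.nan, correct)

    out = trials.copy()
    out["rt_s"] = rt
    out["choice"] = np.where(is_fb, "none", np.where(choice_sign > 0, "right", "left"))
    out["class"] = cls
    out["correct"] = correct
    return out


def _simulate_reward_mode(rat, trials, dt, rng, horizon) -> pd.DataFrame:
    """Sequential simulation: consumed reward feeds back into AI drift."""
    parts = []
    for _, sess in trials.groupby("session", sort=False):
        sess = sess.copy()
        consumed = 0.0
        rows = []
        for _, row in sess.iterrows():
            row = row.copy()
            row["consumed_ul"] = consumed
            one = pd.DataFrame([row])
            v_a = ai_drift_vector(rat, one, "reward")
            out = _simulate_block(rat, one, v_a, dt, rng, horizon)
            rows.append(out)
            r_ul = row["reward_size_ul"]
            if out["correct"].iloc[0] == 1.0 and np.isfinite(r_ul):
                consumed += float(r_ul)
        parts.append(pd.concat(rows, ignore_index=True))
    return pd.concat(parts, ignore_index=True)
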