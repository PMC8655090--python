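"""Maximum-likelihood fitting of the contaminated race model.

The per-trial likelihood is the Huber mixture
``p = c p_C + (1 - c) p_race`` evaluated at the observed withdrawal time
(fixation breaks included as negative times, where the race density
reduces to the AI branch alone).  Fitting maximizes the summed
log-likelihood by bounded Nelder-Mead (logistic transform to the search
box) from multiple screened random starts, with a coarse pass over the
starts, a fine simplex polish of the best two, and a quasi-Newton
refinement of the winner.

Only withdrawal times enter the likelihood -- choices never do -- so
choice behavior (tachometric curves etc.) is a genuine model prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_ndtr, logit, ndtr

from .densities import EASeriesWorkspace, contaminant_pdf, ea_total_pdf_cdf
from .params import FIT_BOUNDS, RatParams, T_CENSOR, T_FIX
from .trials import Trial, ai_drift_vector, normalize_trials, trial_params

__all__ = [
    "FitResult",
    "free_parameters",
    "trial_loglik",
    "loglik_dataset",
    "fit_mle",
    "refit_catch",
    "compare_bic",
]

_DENSITY_FLOOR = 1e-300

# Elapsed-time grid for tabulating the EA density inside the likelihood:
# geometric near the onset (where the density rises super-exponentially),
# linear afterwards; trial RTs are interpolated on it.
_TAU_GRID = np.concatenate(
    [[0.0], np.geomspace(2e-5, 0.02, 48), np.linspace(0.0225, 1.70, 340)]
)


def free_parameters(mode: str) -> list[str]:
    """Names of the free parameters for a fitting mode."""
    base = ["theta_a", "t_a", "nu_e", "theta_e", "t_e", "c", "d", "beta"]
    if mode in ("standard", "unbiased"):
        return ["nu_a0", "nu_trial"] + base
    if mode == "biased":
        return ["nu_a0", "nu_trial"] + base + ["z_e"]
    if mode == "reward":
        return ["w_0", "w_r", "w_t", "w_c"] + base
    raise ValueError(f"unknown fitting mode {mode!r}")


def _drift_mode(mode: str) -> str:
    return "reward" if mode == "reward" else "standard"


def _ai_pdf_cdf_vec(rt: np.ndarray, v_a: np.ndarray, theta: float, t_a: float):
    """Wald pdf/cdf with a per-trial drift vector (log-stabilized cdf)."""
    tau = rt - t_a
    pdf = np.zeros_like(rt)
    cdf = np.zeros_like(rt)
    pos = tau > 0
    tp = tau[pos]
    v = v_a[pos] if np.ndim(v_a) else np.full(tp.shape, v_a)
    sq = np.sqrt(tp)
    pdf[pos] = theta / np.sqrt(2.0 * np.pi * tp**3) * np.exp(
        -((v * tp - theta) ** 2) / (2.0 * tp)
    )
    cdf[pos] = np.clip(
        ndtr((v * tp - theta) / sq) + np.exp(2.0 * v * theta + log_ndtr(-(v * tp + theta) / sq)),
        0.0,
        1.0,
    )
    return pdf, cdf


def _condition_groups(trials: pd.DataFrame):
    """Group trials by the covariates that shape the EA density.

    The labels depend only on the table (not on the parameters), so they
    are computed once and cached on the DataFrame.  With no expectation
    bias the exit law is even in the drift, so opposite-sign strengths
    share a group.
    """
    cache = trials.attrs.get("_psiam_groups")
    if cache is not None and cache[0] == len(trials):
        return cache[1]
    s = trials["strength_signed"].to_numpy(dtype=float)
    bias = trials["bias_sign"].to_numpy(dtype=float)
    delta = trials["onset_shift_s"].to_numpy(dtype=float)
    silent = trials["silent"].to_numpy(dtype=bool)
    s_key = np.where(bias == 0.0, np.abs(s), s)
    keys = np.stack([np.round(s_key, 9), bias, np.round(delta, 9)], axis=1)
    keys[silent] = -99.0  # silent trials: one throwaway group
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    groups = []
    for j, (sj, bj, dj) in enumerate(uniq):
        sel = (inv == j) & ~silent
        if np.any(sel):
            groups.append((np.flatnonzero(sel), float(sj), float(bj), float(dj)))
    trials.attrs["_psiam_groups"] = (len(trials), groups)
    return groups


def _race_pdf_at(rat: RatParams, trials: pd.DataFrame, rt: np.ndarray, mode: str):
    """Race density (pre-mixture) at each trial's withdrawal time.

    Also returns each trial's race-cdf mass inside the analysis support
    ``(-T_fix, 1 s]``, needed for truncation renormalization.
    """
    v_a = ai_drift_vector(rat, trials, _drift_mode(mode))
    p_a, c_a = _ai_pdf_cdf_vec(rt, v_a, rat.theta_a, rat.t_a)
    # window-edge cdfs depend on the trial only through its drift
    v_uniq, v_inv = np.unique(np.round(v_a, 12), return_inverse=True)
    _, c_hi_u = _ai_pdf_cdf_vec(np.full(v_uniq.shape, T_CENSOR), v_uniq, rat.theta_a, rat.t_a)
    c_a_hi = c_hi_u[v_inv]
    if rat.t_a < -T_FIX:  # AI mass can predate the fixation window
        _, c_lo_u = _ai_pdf_cdf_vec(np.full(v_uniq.shape, -T_FIX), v_uniq, rat.theta_a, rat.t_a)
        c_a_lo = c_lo_u[v_inv]
    else:
        c_a_lo = 0.0

    p_e = np.zeros_like(rt)
    c_e = np.zeros_like(rt)
    c_e_hi = np.zeros_like(rt)
    groups = _condition_groups(trials)
    if groups:
        ws = EASeriesWorkspace(_TAU_GRID, rat.theta_e)
        for idx, sj, bj, dj in groups:
            pe_g, ce_g = ws.total_pdf_cdf(rat.nu_e * sj, rat.z_e * bj)
            tau = rt[idx] - dj - rat.t_e
            p_e[idx] = np.interp(tau, _TAU_GRID, pe_g, left=0.0, right=pe_g[-1])
            c_e[idx] = np.interp(tau, _TAU_GRID, ce_g, left=0.0, right=ce_g[-1])
            c_e_hi[idx] = np.interp(T_CENSOR - dj - rat.t_e, _TAU_GRID, ce_g,
                                    left=0.0, right=ce_g[-1])
    pdf = p_a * (1.0 - c_e) + p_e * (1.0 - c_a)
    # race cdf difference between the support edges (EA is zero below -T_fix)
    mass = c_a_hi + c_e_hi - c_a_hi * c_e_hi - c_a_lo
    return pdf, mass


def loglik_dataset(
    rat: RatParams,
    outcomes: pd.DataFrame,
    mode: str = "standard",
    renormalize: bool = True,
) -> tuple[float, int]:
    """Summed per-trial log-likelihood; returns ``(loglik, n_floored)``.

    Withdrawal times outside the analysis support ``(-T_fix, 1 s]`` get
    the density floor (they should have been censored upstream).  By
    default each trial's mixture is renormalized by its exact mass inside
    the support (the proper truncated likelihood, consistent under the
    1 s censoring); ``renormalize=False`` evaluates the raw censored
    density instead.
    """
    rt = outcomes["rt_s"].to_numpy(dtype=float)
    p_race, mass_race = _race_pdf_at(rat, outcomes, rt, mode)
    cont = rat.contaminant()
    p = cont.c * contaminant_pdf(rt, cont) + (1.0 - cont.c) * p_race
    p[(rt <= -T_FIX) | (rt > T_CENSOR) | ~np.isfinite(rt)] = 0.0
    if renormalize:
        # the contaminant integrates to 1 on the support by construction
        p = p / np.maximum(cont.c + (1.0 - cont.c) * mass_race, 1e-12)
    floored = p < _DENSITY_FLOOR
    ll = float(np.sum(np.log(np.maximum(p, _DENSITY_FLOOR))))
    return ll, int(np.count_nonzero(floored))


def trial_loglik(rat: RatParams, trial: Trial, rt_s: float, mode: str = "standard") -> float:
    """Exact single-trial log-density (no grid interpolation).

    Returns ``-inf`` (not an exception) when ``rt_s`` falls outside the
    analysis support.
    """
    if not (-trial.t_fix < rt_s <= T_CENSOR) or not np.isfinite(rt_s):
        return -np.inf
    ai, ea = trial_params(rat, trial, _drift_mode(mode))
    t = np.array([rt_s])
    p_a, c_a = _ai_pdf_cdf_vec(t, np.array([ai.v_a]), ai.theta_a, ai.t_a)
    if ea is None:
        p_race = p_a[0]
    else:
        tau = t - trial.onset_shift_s - ea.t_e
        p_e, c_e = ea_total_pdf_cdf(tau, ea.v_e, ea.theta_e, ea.z_e)
        p_race = p_a[0] * (1.0 - c_e[0]) + p_e[0] * (1.0 - c_a[0])
    cont = rat.contaminant()
    p = cont.c * contaminant_pdf(t, cont)[0] + (1.0 - cont.c) * p_race
    return float(np.log(p)) if p > 0 else -np.inf


# ---------------------------------------------------------------------------
# MLE


@dataclass
class FitResult:
    """MLE output: point estimate, fit quality, per-start diagnostics."""

    params: RatParams
    loglik: float
    bic: float
    n_trials: int
    mode: str
    free_names: list[str]
    starts: pd.DataFrame  # one row per start: x0..., converged, loglik
    pinned: dict[str, bool] = field(default_factory=dict)
    n_floored: int = 0

    @property
    def k(self) -> int:
        return len(self.free_names)

    def params_frame(self) -> pd.DataFrame:
        d = self.params.to_dict()
        return pd.DataFrame(
            {"parameter": list(d), "value": list(d.values()),
             "free": [name in self.free_names for name in d]}
        )


class FitFailure(RuntimeError):
    pass


def _to_box(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * expit(u)


def _from_box(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip((x - lo) / (hi - lo), 1e-4, 1 - 1e-4)
    return logit(frac)


def _valid_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    outcomes = normalize_trials(outcomes)
    rt = outcomes["rt_s"].to_numpy(dtype=float)
    keep = np.isfinite(rt) & (rt > -T_FIX) & (rt <= T_CENSOR)
    return outcomes.loc[keep].reset_index(drop=True)


def fit_mle(
    outcomes: pd.DataFrame,
    mode: str = "standard",
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    rng=None,
    min_trials: int = 500,
    coarse_maxfev: int = 400,
    polish_maxfev: int = 2400,
    fatol: float = 1e-6,
    fixed: dict[str, float] | None = None,
    extra_starts: list[dict[str, float]] | None = None,
) -> FitResult:
    """Bounded multi-start MLE of the contaminated race model.

    All starts (``n_starts`` uniform draws plus any informed
    ``extra_starts``, given as partial parameter dicts) get a coarse
    simplex pass; the best is polished to ``fatol`` on the
    log-likelihood.  Deterministic given ``rng``.
    """
    rng = np.random.default_rng(rng)
    data = _valid_outcomes(outcomes)
    if len(data) < min_trials:
        raise FitFailure(f"need >= {min_trials} valid trials, got {len(data)}")
    names = free_parameters(mode)
    allb = dict(FIT_BOUNDS)
    if bounds:
        allb.update(bounds)
    lo = np.array([allb[n][0] for n in names])
    hi = np.array([allb[n][1] for n in names])
    base = dict(fixed or {})
    if mode in ("standard", "unbiased"):
        base.setdefault("z_e", 0.0)
    if mode == "reward":
        base.setdefault("nu_trial", 0.0)

    def make_rat(x: np.ndarray) -> RatParams:
        return RatParams(**{**base, **dict(zip(names, x))})

    def nll(u: np.ndarray) -> float:
        ll, _ = loglik_dataset(make_rat(_to_box(u, lo, hi)), data, mode)
        return -ll

    # screen many cheap uniform draws, keep the most promising as simplex
    # starts (random initial points in the bounded space, triaged)
    n_screen = min(max(30 * n_starts, 60), 300)
    screened = [lo + (hi - lo) * rng.uniform(0.02, 0.98, size=len(names))
                for _ in range(n_screen)]
    screen_nll = [nll(_from_box(x, lo, hi)) for x in screened]
    order = np.argsort(screen_nll)
    start_points = [screened[j] for j in order[:n_starts]]
    mid = 0.5 * (lo + hi)
    for seed_dict in extra_starts or []:
        x0 = np.array([seed_dict.get(nme, m) for nme, m in zip(names, mid)])
        start_points.append(np.clip(x0, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo)))

    rows = []
    results = []
    for i, x0 in enumerate(start_points):
        res = minimize(
            nll,
            _from_box(x0, lo, hi),
            method="Nelder-Mead",
            options={"maxfev": coarse_maxfev, "fatol": 5e-2, "xatol": 1e-3,
                     "adaptive": True},
        )
        rows.append(
            {"start": i, "loglik": -res.fun, "converged": bool(res.success),
             **{f"x0_{n}": v for n, v in zip(names, x0)}}
        )
        results.append(res)
    results = [r for r in results if np.isfinite(r.fun)]
    if not results:
        raise FitFailure("all starts failed to produce a finite likelihood")
    results.sort(key=lambda r: r.fun)
    # polish the two best coarse optima; restart the winner once with a
    # fresh simplex (recovers from degenerate simplex collapse)
    res = None
    for cand in results[:2]:
        pol = minimize(
            nll,
            cand.x,
            method="Nelder-Mead",
            options={"maxfev": polish_maxfev, "fatol": fatol, "xatol": 1e-5,
                     "adaptive": True},
        )
        if res is None or pol.fun < res.fun:
            res = pol
    # quasi-Newton refinement in the unconstrained space: the simplex
    # stalls on the long (theta_A, nu_A0, t_A) ridge that BFGS tracks;
    # restart until converged (each restart resets the Hessian estimate,
    # which recovers from early line-search stalls)
    for _ in range(4):
        refined = minimize(
            nll, res.x, method="BFGS", options={"maxiter": 80, "gtol": 1e-5}
        )
        if np.isfinite(refined.fun) and refined.fun <= res.fun:
            improved = res.fun - refined.fun
            res = refined
            if improved < 0.05:
                break
        else:
            break
    x = _to_box(res.x, lo, hi)
    rat = make_rat(x)
    ll, n_floored = loglik_dataset(rat, data, mode)
    n = len(data)
    bic = len(names) * np.log(n) - 2.0 * ll
    pinned = {
        nme: bool(xi - l < 1e-3 * (h - l) or h - xi < 1e-3 * (h - l))
        for nme, xi, l, h in zip(names, x, lo, hi)
    }
    return FitResult(
        params=rat, loglik=ll, bic=bic, n_trials=n, mode=mode,
        free_names=names, starts=pd.DataFrame(rows), pinned=pinned,
        n_floored=n_floored,
    )


def fit_reward_model(outcomes: pd.DataFrame, rng=None, n_starts: int = 5, **kw) -> FitResult:
    """Reward-model fit seeded from a standard-mode prefit.

    The 12-dimensional reward likelihood is hard for random-start simplex
    alone; the standard-mode drift (affine in trial index) approximates
    the reward drift well enough that its fit provides a reliable warm
    start for the shared parameters.
    """
    rng = np.random.default_rng(rng)
    pre = fit_mle(outcomes, mode="standard", n_starts=n_starts, rng=rng, **kw)
    p = pre.params
    init = {n: getattr(p, n) for n in ["theta_a", "t_a", "nu_e", "theta_e", "t_e", "c", "d", "beta"]}
    init.update(w_0=max(p.nu_a0 - 0.24, 0.01), w_r=0.01, w_t=p.nu_trial, w_c=-2e-5)
    return fit_mle(
        outcomes, mode="reward", n_starts=n_starts, rng=rng, extra_starts=[init], **kw
    )


def refit_catch(
    rat: RatParams,
    outcomes: pd.DataFrame,
    free: tuple[str, ...] = ("t_e",),
    mode: str = "standard",
) -> dict:
    """Re-fit a subset of {t_e, nu_e} on one onset-shift condition.

    The pure-shift prediction (EA origin translated by the table's
    ``onset_shift_s``, all parameters from the standard fit) is the
    baseline; the returned dict reports the parameter changes and the
    log-likelihood gain of the refit over that baseline.
    """
    if not set(free) <= {"t_e", "nu_e"}:
        raise ValueError("free must be a subset of {'t_e', 'nu_e'}")
    data = _valid_outcomes(outcomes)
    ll_shift, _ = loglik_dataset(rat, data, mode)
    out = {"ll_shift": ll_shift, "dt_e": 0.0, "dnu_e": 0.0,
           "ll_refit": ll_shift, "dll": 0.0, "params": rat}
    if not free:
        return out
    names = list(free)
    # refit windows: generous around the standard-fit values, the latency
    # allowed to grow well beyond the standard search box (attentional
    # slowing under advanced stimuli can exceed it)
    box = {"t_e": (0.005, 0.300), "nu_e": (0.1, 15.0)}
    lo = np.array([box[n][0] for n in names])
    hi = np.array([box[n][1] for n in names])

    def nll(u):
        ll, _ = loglik_dataset(rat.replace(**dict(zip(names, _to_box(u, lo, hi)))), data, mode)
        return -ll

    x0 = np.array([getattr(rat, n) for n in names])
    res = minimize(
        nll, _from_box(x0, lo, hi), method="Nelder-Mead",
        options={"maxfev": 2000, "fatol": 1e-8, "xatol": 1e-6},
    )
    x = _to_box(res.x, lo, hi)
    fitted = rat.replace(**dict(zip(names, x)))
    ll_refit, _ = loglik_dataset(fitted, data, mode)
    out.update(
        dt_e=float(fitted.t_e - rat.t_e),
        dnu_e=float(fitted.nu_e - rat.nu_e),
        ll_refit=ll_refit,
        dll=ll_refit - ll_shift,
        params=fitted,
    )
    return out


def compare_bic(fit_a, fit_b) -> float:
    """``BIC_b - BIC_a`` on the same outcome set; positive favors model a."""
    return float(fit_b.bic - fit_a.bic)
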