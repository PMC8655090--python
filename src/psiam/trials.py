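"""Mapping from per-trial covariates to process parameters.

A trial table has one row per center-port withdrawal.  Canonical columns
(missing optional columns get neutral defaults):

    session, trial_index, strength_signed, bias_sign, reward_size_ul,
    consumed_ul, onset_shift_s, silent, rt_s, choice, correct

The subject-level coefficients (:class:`~psiam.params.RatParams`) are
turned into the trial's process parameters:

* AI drift: ``V_A = nu_a0 + nu_trial * k`` (standard mode) or
  ``V_A = w_0 + w_r * r + w_t * k + w_c * C`` (reward mode),
* EA drift: ``V_E = nu_e * S`` for signed strength ``S``,
* EA offset: ``Z_E = z_e * b_k`` for the expectation sign ``b_k``,
* the stimulus-onset shift ``Delta`` translates only the EA time origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AIParams, EAParams, RatParams, T_FIX

__all__ = [
    "Trial",
    "TRIAL_COLUMNS",
    "OUTCOME_COLUMNS",
    "trial_params",
    "ai_drift",
    "read_trials",
    "write_trials",
    "consumed_from_outcomes",
]

TRIAL_COLUMNS = [
    "session",
    "trial_index",
    "strength_signed",
    "bias_sign",
    "reward_size_ul",
    "consumed_ul",
    "onset_shift_s",
    "silent",
    "rt_s",
    "choice",
    "correct",
]

OUTCOME_COLUMNS = TRIAL_COLUMNS + ["class"]

_OPTIONAL_DEFAULTS = {
    "session": 0,
    "bias_sign": 0,
    "reward_size_ul": np.nan,
    "consumed_ul": 0.0,
    "onset_shift_s": 0.0,
    "silent": False,
    "rt_s": np.nan,
    "choice": "none",
    "correct": np.nan,
}


@dataclass(frozen=True)
class Trial:
    """Covariates of a single trial."""

    index: int  # within-session counter, >= 1
    strength_signed: float = 0.0  # S in [-1, 1]; sign = rewarded side (right +)
    bias_sign: int = 0  # b_k in {-1, 0, +1}
    reward_size_ul: float = np.nan
    consumed_ul: float = 0.0
    onset_shift_s: float = 0.0  # Delta, s
    silent: bool = False
    t_fix: float = T_FIX

    def __post_init__(self) -> None:
        if abs(self.strength_signed) > 1 + 1e-12:
            raise ValueError("|strength_signed| must be <= 1")
        if self.index < 1:
            raise ValueError("trial index must be >= 1")


class ConfigurationError(ValueError):
    """Missing covariates or coefficients for the requested mode."""


def ai_drift(rat: RatParams, trial: Trial, mode: str = "standard") -> float:
    """AI drift for one trial under the selected drift model."""
    if mode == "standard":
        return rat.nu_a0 + rat.nu_trial * trial.index
    if mode == "reward":
        if any(w is None for w in (rat.w_0, rat.w_r, rat.w_t, rat.w_c)):
            raise ConfigurationError("reward mode requires w_0, w_r, w_t, w_c")
        if not np.isfinite(trial.reward_size_ul):
            raise ConfigurationError("reward mode requires reward_size_ul")
        return (
            rat.w_0
            + rat.w_r * trial.reward_size_ul
            + rat.w_t * trial.index
            + rat.w_c * trial.consumed_ul
        )
    raise ConfigurationError(f"unknown drift mode {mode!r}")


def trial_params(
    rat: RatParams, trial: Trial, mode: str = "standard"
) -> tuple[AIParams, EAParams | None]:
    """Process parameters for one trial; silent trials have no EA."""
    ai = AIParams(v_a=ai_drift(rat, trial, mode), theta_a=rat.theta_a, t_a=rat.t_a)
    if trial.silent:
        return ai, None
    ea = EAParams(
        v_e=rat.nu_e * trial.strength_signed,
        theta_e=rat.theta_e,
        z_e=rat.z_e * trial.bias_sign,
        t_e=rat.t_e,
    )
    return ai, ea


def ai_drift_vector(rat: RatParams, trials: pd.DataFrame, mode: str = "standard") -> np.ndarray:
    """Vectorized AI drift over a trial table."""
    k = trials["trial_index"].to_numpy(dtype=float)
    if mode == "standard":
        return rat.nu_a0 + rat.nu_trial * k
    if mode == "reward":
        if any(w is None for w in (rat.w_0, rat.w_r, rat.w_t, rat.w_c)):
            raise ConfigurationError("reward mode requires w_0, w_r, w_t, w_c")
        r = trials["reward_size_ul"].to_numpy(dtype=float)
        cons = trials["consumed_ul"].to_numpy(dtype=float)
        if np.any(~np.isfinite(r)):
            raise ConfigurationError("reward mode requires reward_size_ul")
        return rat.w_0 + rat.w_r * r + rat.w_t * k + rat.w_c * cons
    raise ConfigurationError(f"unknown drift mode {mode!r}")


def normalize_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Fill optional columns with neutral defaults; validate the schema."""
    df = df.copy()
    if "trial_index" not in df or "strength_signed" not in df:
        raise ValueError(
            "trial table needs at least trial_index and strength_signed; "
            f"expected columns: {TRIAL_COLUMNS}"
        )
    for col, default in _OPTIONAL_DEFAULTS.items():
        if col not in df:
            df[col] = default
    df["silent"] = df["silent"].astype(bool)
    df["bias_sign"] = df["bias_sign"].fillna(0).astype(int)
    return df


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(OUTCOME_COLUMNS) - {"target_side"}
    if unknown:
        raise ValueError(
            f"unknown columns {sorted(unknown)}; expected a subset of {OUTCOME_COLUMNS}"
        )
    return normalize_trials(df)


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def consumed_from_outcomes(outcomes: pd.DataFrame) -> np.ndarray:
    """Cumulative reward earned *before* each trial, per session (uL)."""
    rewarded = (
        outcomes["correct"].fillna(False).astype(bool).to_numpy()
        * outcomes["reward_size_ul"].fillna(0.0).to_numpy()
    )
    out = np.zeros(len(outcomes))
    for _, idx in outcomes.groupby("session").indices.items():
        cum = np.cumsum(rewarded[idx])
        out[idx] = np.concatenate([[0.0], cum[:-1]])
    return out
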