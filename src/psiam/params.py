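"""Parameter containers and fitting bounds for the PSIAM race model.

All times are in seconds and are referenced to the *scheduled* stimulus
onset of a standard trial (fixation onset is therefore at ``-T_FIX``).
Drifts and bounds are "reduced" quantities: the diffusion noise of both
the action-initiation (AI) and evidence-accumulation (EA) processes is
fixed to 1, so drifts carry units of 1/s and bounds are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "T_FIX",
    "T_CENSOR",
    "AIParams",
    "EAParams",
    "ContaminantParams",
    "RatParams",
    "EDDMParams",
    "FIT_BOUNDS",
    "EDDM_FIT_BOUNDS",
    "ParameterDomainError",
]

#: Fixation duration of a standard trial, seconds.
T_FIX = 0.3
#: Censoring time: responses slower than this are removed from analysis.
T_CENSOR = 1.0


class ParameterDomainError(ValueError):
    """A parameter violates its domain (e.g. non-positive bound height)."""


@dataclass(frozen=True)
class AIParams:
    """Action-initiation process: single-bound drift diffusion.

    First-passage times follow an inverse-Gaussian (Wald) law shifted by
    the total latency ``t_a`` (afferent + motor), which may be negative
    because the process starts ramping during the fixation period.
    """

    v_a: float  # reduced drift, 1/s
    theta_a: float  # reduced bound height, dimensionless, > 0
    t_a: float = 0.0  # total latency relative to scheduled stimulus onset, s

    def __post_init__(self) -> None:
        if not (self.theta_a > 0):
            raise ParameterDomainError(f"theta_a must be > 0, got {self.theta_a}")
        if any(math.isnan(v) for v in (self.v_a, self.theta_a, self.t_a)):
            raise ParameterDomainError("AIParams fields must not be NaN")


@dataclass(frozen=True)
class EAParams:
    """Evidence-accumulation process: symmetric two-bound drift diffusion.

    The accumulator starts at ``z_e`` (in (-theta_e, theta_e)) and is
    absorbed at +/- ``theta_e``; ``t_e`` is the total latency (afferent +
    motor) relative to the actual stimulus onset of the trial.
    """

    v_e: float  # reduced drift, 1/s
    theta_e: float  # reduced symmetric bound, > 0
    z_e: float = 0.0  # starting offset, in (-theta_e, theta_e)
    t_e: float = 0.05  # total latency, s, > 0

    def __post_init__(self) -> None:
        if not (self.theta_e > 0):
            raise ParameterDomainError(f"theta_e must be > 0, got {self.theta_e}")
        if not (-self.theta_e < self.z_e < self.theta_e):
            raise ParameterDomainError(
                f"z_e must lie strictly inside (-theta_e, theta_e); "
                f"got z_e={self.z_e}, theta_e={self.theta_e}"
            )
        if any(math.isnan(v) for v in (self.v_e, self.theta_e, self.z_e, self.t_e)):
            raise ParameterDomainError("EAParams fields must not be NaN")


@dataclass(frozen=True)
class ContaminantParams:
    """Huber-style contaminant mixture: truncated exponential + uniform.

    The exponential decays from the left edge of the support (fixation
    onset) with rate ``beta`` and is renormalized on ``[t_lo, t_hi]``;
    ``d`` is the exponential-vs-uniform weight and ``c`` the overall
    contaminant fraction of responses.
    """

    c: float = 0.0  # contaminant fraction, [0, 0.5]
    d: float = 0.5  # exponential-vs-uniform mix, [0, 1]
    beta: float = 10.0  # exponential rate, 1/s, >= 0
    t_lo: float = -T_FIX
    t_hi: float = T_CENSOR

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 1.0):
            raise ParameterDomainError(f"c must be in [0, 1], got {self.c}")
        if not (0.0 <= self.d <= 1.0):
            raise ParameterDomainError(f"d must be in [0, 1], got {self.d}")
        if self.beta < 0:
            raise ParameterDomainError(f"beta must be >= 0, got {self.beta}")
        if not (self.t_hi > self.t_lo):
            raise ParameterDomainError("contaminant support must have t_hi > t_lo")

    @property
    def ctt(self) -> float:
        """Height of the uniform component, 1/s."""
        return 1.0 / (self.t_hi - self.t_lo)


@dataclass(frozen=True)
class RatParams:
    """Full subject-level parameter vector.

    In *standard* mode the AI drift on trial ``k`` is
    ``V_A = nu_a0 + nu_trial * k``; in *reward* mode it is
    ``V_A = w_0 + w_r * r + w_t * k + w_c * C`` with ``r`` the reward
    size (uL) and ``C`` the reward consumed so far (uL).  The EA drift is
    ``V_E = nu_e * S`` for signed strength ``S`` and the starting offset
    is ``Z_E = z_e * b_k`` for the expectation sign ``b_k``.
    """

    nu_a0: float = 6.0  # AI drift intercept, 1/s
    nu_trial: float = 0.0  # AI drift slope per trial, 1/(s*trial)
    theta_a: float = 2.0
    t_a: float = -0.1
    nu_e: float = 5.0  # EA drift per unit strength, 1/s
    theta_e: float = 0.8
    t_e: float = 0.05
    z_e: float = 0.0  # expectation offset magnitude (0 in unbiased mode)
    c: float = 0.05
    d: float = 0.5
    beta: float = 10.0
    # reward-model drift weights (replace nu_a0/nu_trial when used)
    w_0: float | None = None  # intercept, 1/s
    w_r: float | None = None  # per uL of reward size
    w_t: float | None = None  # per trial
    w_c: float | None = None  # per uL consumed

    def contaminant(self) -> ContaminantParams:
        return ContaminantParams(c=self.c, d=self.d, beta=self.beta)

    def replace(self, **kw) -> "RatParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RatParams":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class EDDMParams:
    """Extended drift-diffusion baseline: a single accumulator that
    integrates internal noise (variance ``sigma2_i``, drift 0) from
    fixation onset plus latency, switching to stimulus-driven drift
    ``nu_e * S`` with unit noise variance once stimulus information
    arrives; absorbing bounds at +/- ``theta``.
    """

    sigma2_i: float = 0.2  # pre-stimulus noise variance, 1/s
    t_latency: float = 0.1  # t_aff(internal) + t_motor, s
    nu_e: float = 5.0  # drift per unit strength, 1/s
    t_e: float = 0.05  # non-decision time of the stimulus pathway, s
    theta: float = 1.0  # bound, dimensionless
    c: float = 0.0
    d: float = 0.5
    beta: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma2_i < 0:
            raise ParameterDomainError("sigma2_i must be >= 0")
        if not (self.theta > 0):
            raise ParameterDomainError("theta must be > 0")

    def contaminant(self) -> ContaminantParams:
        return ContaminantParams(c=self.c, d=self.d, beta=self.beta)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: MLE search box, per parameter (units as in :class:`RatParams`).
FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu_a0": (0.0, 12.0),
    "nu_trial": (-2e-2, 1e-2),
    "theta_a": (0.1, 10.0),
    "t_a": (-0.600, 0.300),
    "nu_e": (2.0, 10.0),
    "theta_e": (0.1, 1.2),
    "t_e": (0.035, 0.075),
    "z_e": (-1.0 / 2.0, 1.0 / 3.0),
    "c": (0.0, 0.5),
    "d": (0.0, 1.0),
    "beta": (0.0, 50.0),
    # reward-model drift weights; ranges keep V_A within ~[0, 12] 1/s
    # over realistic covariates (r <= 48 uL, k <= ~1000, C <= ~15000 uL)
    "w_0": (0.0, 12.0),
    "w_r": (-0.1, 0.1),
    "w_t": (-2e-2, 1e-2),
    "w_c": (-1e-3, 1e-3),
}

#: Search box for the extended-DDM baseline.
EDDM_FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma2_i": (1e-3, 2.0),
    "t_latency": (0.0, 0.30),
    "nu_e": (2.0, 10.0),
    "t_e": (0.035, 0.075),
    "theta": (0.3, 4.0),
    "c": (0.0, 0.5),
    "d": (0.0, 1.0),
    "beta": (0.0, 50.0),
}
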