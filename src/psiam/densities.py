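"""Closed-form first-passage densities of the race model components.

The action-initiation (AI) process alone produces inverse-Gaussian
(Wald) first-passage times; the evidence-accumulation (EA) process alone
produces the two-bound drift-diffusion first-passage law, evaluated by
the classic large-time Fourier series with term-wise analytic
integration for the cdf.  The race of the two independent processes has

    p = p_A (1 - c_E) + p_E (1 - c_A)
    c = c_A + c_E - c_A c_E

and rare contaminant responses enter as a Huber-style mixture
``p = c p_C + (1 - c) p_model`` with a truncated-exponential + uniform
contaminant density.

All densities are tabulated on a caller-supplied time grid (seconds,
relative to the scheduled stimulus onset) as a :class:`DensityGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr

from .params import (
    AIParams,
    ContaminantParams,
    EAParams,
    ParameterDomainError,
    T_CENSOR,
    T_FIX,
)

__all__ = [
    "DensityGrid",
    "default_grid",
    "ai_density",
    "ea_density",
    "race_density",
    "EASeriesWorkspace",
    "contaminant_pdf",
    "contaminant_cdf",
    "contaminated_density",
    "ea_exit_probability_lower",
]

# Truncation control for the large-time EA series: keep terms until the
# slowest-decaying retained exponent is below exp(-_SERIES_EXP_CUT).
_SERIES_EXP_CUT = 45.0
_SERIES_KMAX = 10_000
_SERIES_KMIN = 10
# Below this elapsed time the series value is numerically indistinguishable
# from zero for any parameters inside the fitting box.
_TAU_FLOOR = 1e-5


@dataclass
class DensityGrid:
    """A model component tabulated on a strictly increasing time grid."""

    times: np.ndarray  # seconds
    pdf: np.ndarray  # 1/s
    cdf: np.ndarray  # in [0, 1]
    component: str = "mixture"
    #: for race grids: share of density due to the AI (proactive) branch
    proactive_share: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pdf = np.asarray(self.pdf, dtype=float)
        self.cdf = np.asarray(self.cdf, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-d grid")
        if self.pdf.shape != self.times.shape or self.cdf.shape != self.times.shape:
            raise ValueError("pdf/cdf must match the time grid shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pdf": self.pdf,
                "cdf": self.cdf,
                "component": self.component,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DensityGrid":
        df = pd.read_csv(path)
        comp = str(df["component"].iloc[0]) if "component" in df else "mixture"
        return cls(df["time_s"].to_numpy(), df["pdf"].to_numpy(), df["cdf"].to_numpy(), comp)

    def interp_pdf(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.pdf, left=0.0, right=0.0)

    def interp_cdf(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.cdf, left=0.0, right=float(self.cdf[-1]))


def default_grid(t_lo: float = -T_FIX, t_hi: float = T_CENSOR, dt: float = 1e-3) -> np.ndarray:
    """Default tabulation grid: 1 ms steps over the analysis window."""
    n = int(round((t_hi - t_lo) / dt))
    return t_lo + dt * np.arange(n + 1)


def _check_grid(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2 or not np.all(np.isfinite(t)):
        raise ValueError("time grid must be a finite 1-d array with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return t


# ---------------------------------------------------------------------------
# AI process: inverse-Gaussian first-passage law


def ai_pdf(t, params: AIParams) -> np.ndarray:
    """Wald pdf of the AI first-passage time at times ``t`` (vectorized)."""
    t = np.asarray(t, dtype=float)
    if np.any(np.isnan(t)):
        raise ValueError("NaN in time input")
    tau = t - params.t_a
    out = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    # theta / sqrt(2 pi tau^3) * exp(-(V tau - theta)^2 / (2 tau))
    arg = -((params.v_a * tp - params.theta_a) ** 2) / (2.0 * tp)
    out[pos] = params.theta_a / np.sqrt(2.0 * np.pi * tp**3) * np.exp(arg)
    return out


def ai_cdf(t, params: AIParams) -> np.ndarray:
    """Wald cdf of the AI first-passage time (stable for any drift sign).

    For negative drift the process reaches the bound only with
    probability ``exp(2 v theta) < 1``; the cdf saturates there.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.isnan(t)):
        raise ValueError("NaN in time input")
    tau = t - params.t_a
    out = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    v, th = params.v_a, params.theta_a
    sq = np.sqrt(tp)
    term1 = ndtr((v * tp - th) / sq)
    # exp(2 v theta) * Phi(-(v tau + theta)/sqrt(tau)), computed in logs to
    # survive large |v theta|
    term2 = np.exp(2.0 * v * th + log_ndtr(-(v * tp + th) / sq))
    out[pos] = np.clip(term1 + term2, 0.0, 1.0)
    return out


def ai_density(t, params: AIParams) -> DensityGrid:
    """Tabulated pdf/cdf of the AI process alone."""
    t = _check_grid(t)
    return DensityGrid(t, ai_pdf(t, params), ai_cdf(t, params), component="AI_alone")


# ---------------------------------------------------------------------------
# EA process: two-bound drift diffusion (large-time series)


def _series_k(theta_e: float, tau_min: float) -> int:
    """Number of Fourier terms so the first dropped term is < exp(-45)."""
    a = 2.0 * theta_e
    k = int(np.ceil(a / np.pi * np.sqrt(2.0 * _SERIES_EXP_CUT / max(tau_min, _TAU_FLOOR))))
    return int(np.clip(k, _SERIES_KMIN, _SERIES_KMAX))


def ea_exit_probability_lower(v_e: float, theta_e: float, z_e: float) -> float:
    """Probability that the EA exits through the *lower* bound.

    Classic two-barrier absorption probability for a unit-noise
    diffusion with drift ``v_e`` started at ``z_e`` between ``+/-theta_e``.
    """
    v, th, z = v_e, theta_e, z_e
    if abs(v) < 1e-12:
        return float((th - z) / (2.0 * th))
    # (e^{-2 v z} - e^{-2 v th}) / (e^{2 v th} - e^{-2 v th}), log-stabilized
    num = np.exp(-2 * v * z - 2 * v * th) - np.exp(-4 * v * th)
    den = 1.0 - np.exp(-4 * v * th)
    return float(num / den)


class EASeriesWorkspace:
    """Precomputed Fourier machinery for one ``(tau grid, theta)`` pair.

    The decay matrices ``exp(-(k pi / a)^2 tau / 2)`` depend only on the
    grid and the bound, so evaluating the series for many drifts and
    starting points (as the likelihood does) reuses them.  The grid is
    processed in decade bands of elapsed time, each with its own
    truncation: the number of terms needed falls off as 1/sqrt(tau), and
    the first dropped term of every band is below ``exp(-45)``.
    """

    _EDGES = np.array([0.0, 1e-4, 1e-3, 1e-2, 1e-1, np.inf])

    def __init__(self, tau: np.ndarray, theta: float):
        self.tau = np.asarray(tau, dtype=float)
        self.theta = theta
        self.a = 2.0 * theta
        # below _TAU_FLOOR the exact density is indistinguishable from zero
        # for any parameters in the search box, and the series needs more
        # terms than the cap; treat it as zero support
        self.pos = self.tau > _TAU_FLOOR
        tp_all = self.tau[self.pos]
        self.bands = []
        for lo_e, hi_e in zip(self._EDGES[:-1], self._EDGES[1:]):
            sel = (tp_all > lo_e) & (tp_all <= hi_e)
            if not np.any(sel):
                continue
            tp = tp_all[sel]
            K = _series_k(theta, float(tp.min()))
            k = np.arange(1, K + 1)
            kpia2 = 0.5 * (k * np.pi / self.a) ** 2  # lam_k minus the v^2/2 part
            decay = np.exp(-np.outer(kpia2, tp))
            self.bands.append((sel, tp, k, kpia2, decay))

    def lower_pdf_cdf(self, v: float, z: float):
        """Lower-bound exit pdf/cdf at the workspace grid for one (v, z).

        The cdf is the exact two-barrier absorption probability minus the
        term-wise integrated series tail, so both ends of the support are
        exact.
        """
        a, theta = self.a, self.theta
        w = (z + theta) / a  # relative start in (0, 1)
        pdf = np.zeros_like(self.tau)
        cdf = np.zeros_like(self.tau)
        if not np.any(self.pos):
            return pdf, cdf
        p_inf = ea_exit_probability_lower(v, theta, z)
        npos = int(np.count_nonzero(self.pos))
        pdf_pos = np.empty(npos)
        cdf_pos = np.empty(npos)
        for sel, tp, k, kpia2, decay in self.bands:
            sink = np.sin(k * np.pi * w)
            vfac = np.exp(-0.5 * v**2 * tp)
            drift_fac = np.exp(-v * a * w) * vfac
            pdf_pos[sel] = np.clip(np.pi / a**2 * drift_fac * ((k * sink) @ decay), 0.0, None)
            # cdf(tau) = P(exit lower)
            #   - pi/a^2 e^{-vaw} sum_k k sin(k pi w) e^{-lam_k tau} / lam_k
            lam = 0.5 * v**2 + kpia2
            tail = ((k * sink / lam) @ decay) * vfac
            cdf_pos[sel] = np.clip(p_inf - np.pi / a**2 * np.exp(-v * a * w) * tail, 0.0, p_inf)
        pdf[self.pos] = pdf_pos
        cdf[self.pos] = cdf_pos
        return pdf, cdf

    def total_pdf_cdf(self, v: float, z: float):
        """Exit pdf/cdf summed over both bounds (reflection for the upper)."""
        p_lo, c_lo = self.lower_pdf_cdf(v, z)
        if v == 0.0 and z == 0.0:  # symmetric: both bounds identical
            return 2.0 * p_lo, 2.0 * c_lo
        p_up, c_up = self.lower_pdf_cdf(-v, -z)
        return p_lo + p_up, c_lo + c_up


def _ea_lower_pdf_cdf(tau: np.ndarray, v: float, theta: float, z: float):
    """Lower-bound exit pdf and cdf on elapsed times ``tau``."""
    return EASeriesWorkspace(tau, theta).lower_pdf_cdf(v, z)


def ea_density(
    t, params: EAParams, delta: float = 0.0
) -> tuple[DensityGrid, DensityGrid]:
    """Per-bound first-passage densities of the EA process alone.

    ``delta`` shifts the stimulus onset (advanced/delayed trials); the
    density is zero for ``t <= delta + t_e``.  Returns the upper- and
    lower-bound :class:`DensityGrid` pair; the upper-bound density is the
    lower-bound one under the reflection ``(v, z) -> (-v, -z)``.
    """
    t = _check_grid(t)
    tau = t - delta - params.t_e
    p_lo, c_lo = _ea_lower_pdf_cdf(tau, params.v_e, params.theta_e, params.z_e)
    p_up, c_up = _ea_lower_pdf_cdf(tau, -params.v_e, params.theta_e, -params.z_e)
    return (
        DensityGrid(t, p_up, c_up, component="EA_upper"),
        DensityGrid(t, p_lo, c_lo, component="EA_lower"),
    )


def ea_total_pdf_cdf(tau: np.ndarray, v: float, theta: float, z: float):
    """Total EA exit pdf/cdf (both bounds) on elapsed times ``tau``."""
    p_lo, c_lo = _ea_lower_pdf_cdf(tau, v, theta, z)
    p_up, c_up = _ea_lower_pdf_cdf(tau, -v, theta, -z)
    return p_lo + p_up, c_lo + c_up


# ---------------------------------------------------------------------------
# Race combination


def race_density(
    t, ai: AIParams, ea: EAParams | None, delta: float = 0.0
) -> DensityGrid:
    """Density of the first process (AI vs EA) to reach its bound.

    With the EA disabled (silent trials, ``ea is None``) the race
    degenerates to the AI density.  The returned grid carries the
    proactive share ``p_A (1 - c_E) / p`` used for response-class
    attribution.
    """
    t = _check_grid(t)
    p_a = ai_pdf(t, ai)
    c_a = ai_cdf(t, ai)
    if ea is None:
        g = DensityGrid(t, p_a, c_a, component="race")
        g.proactive_share = np.where(p_a > 0, 1.0, np.nan)
        return g
    tau = t - delta - ea.t_e
    p_e, c_e = ea_total_pdf_cdf(tau, ea.v_e, ea.theta_e, ea.z_e)
    pdf = p_a * (1.0 - c_e) + p_e * (1.0 - c_a)
    cdf = c_a + c_e - c_a * c_e
    g = DensityGrid(t, pdf, cdf, component="race")
    with np.errstate(invalid="ignore", divide="ignore"):
        g.proactive_share = np.where(pdf > 0, p_a * (1.0 - c_e) / pdf, np.nan)
    return g


# ---------------------------------------------------------------------------
# Contaminant mixture


def contaminant_pdf(t, cont: ContaminantParams) -> np.ndarray:
    """Contaminant density: truncated exponential (decaying from the left
    edge of the support, i.e. fixation onset) mixed with a uniform."""
    t = np.asarray(t, dtype=float)
    span = cont.t_hi - cont.t_lo
    inside = (t >= cont.t_lo) & (t <= cont.t_hi)
    out = np.zeros_like(t)
    if cont.beta * span < 1e-9:  # exponential degenerates to uniform
        expo = np.full_like(t, 1.0 / span)
    else:
        norm = -np.expm1(-cont.beta * span)  # 1 - exp(-beta * span)
        expo = cont.beta * np.exp(-cont.beta * (t - cont.t_lo)) / norm
    out[inside] = cont.d * expo[inside] + (1.0 - cont.d) / span
    return out


def contaminant_cdf(t, cont: ContaminantParams) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    span = cont.t_hi - cont.t_lo
    x = np.clip(t - cont.t_lo, 0.0, span)
    if cont.beta * span < 1e-9:
        expo = x / span
    else:
        norm = -np.expm1(-cont.beta * span)
        expo = -np.expm1(-cont.beta * x) / norm
    return cont.d * expo + (1.0 - cont.d) * x / span


def contaminated_density(model: DensityGrid, cont: ContaminantParams) -> DensityGrid:
    """Mix a model density with the contaminant: ``c p_C + (1 - c) p``."""
    if not (0.0 <= cont.c <= 1.0) or not (0.0 <= cont.d <= 1.0):
        raise ParameterDomainError("contaminant weights must lie in [0, 1]")
    pdf = cont.c * contaminant_pdf(model.times, cont) + (1.0 - cont.c) * model.pdf
    cdf = cont.c * contaminant_cdf(model.times, cont) + (1.0 - cont.c) * model.cdf
    return DensityGrid(model.times, pdf, cdf, component="mixture")
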