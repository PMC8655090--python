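"""Parameter-free predictions for catch trials.

From a standard-condition fit, the model predicts silent-trial RTs as the
AI density alone (no stimulus means no EA, so every non-contaminant
response is proactive) and advanced/delayed-trial RTs as the race with
the EA time origin translated by the onset shift, the AI untouched.
These predictions cost no extra parameters; the advanced-stimulus
variant with a re-fitted EA latency lives in
:func:`psiam.fit.refit_catch`.
"""

from __future__ import annotations

import numpy as np

from .densities import (
    DensityGrid,
    ai_density,
    contaminated_density,
    default_grid,
    race_density,
)
from .params import AIParams, EAParams, RatParams

__all__ = ["predict_silent", "predict_shifted", "standard_processes"]


def standard_processes(
    rat: RatParams, trial_index: int = 1, strength: float = 1.0, bias_sign: int = 0
) -> tuple[AIParams, EAParams]:
    """AI/EA parameters of a reference standard trial."""
    ai = AIParams(
        v_a=rat.nu_a0 + rat.nu_trial * trial_index, theta_a=rat.theta_a, t_a=rat.t_a
    )
    ea = EAParams(
        v_e=rat.nu_e * strength, theta_e=rat.theta_e,
        z_e=rat.z_e * bias_sign, t_e=rat.t_e,
    )
    return ai, ea


def predict_silent(
    rat: RatParams,
    include_contaminants: bool = False,
    times: np.ndarray | None = None,
    trial_index: int = 1,
) -> DensityGrid:
    """Predicted RT density for silent catch trials: the AI alone."""
    t = default_grid() if times is None else np.asarray(times, dtype=float)
    ai, _ = standard_processes(rat, trial_index)
    g = ai_density(t, ai)
    if include_contaminants:
        g = contaminated_density(g, rat.contaminant())
    g.component = "silent_prediction"
    return g


def predict_shifted(
    rat: RatParams,
    delta: float,
    include_contaminants: bool = False,
    times: np.ndarray | None = None,
    trial_index: int = 1,
    strength: float = 1.0,
) -> DensityGrid:
    """Predicted RT density with the stimulus onset shifted by ``delta``.

    Pure translation of the EA time origin (``delta < 0`` advanced,
    ``> 0`` delayed); shifted catch trials are run at full stimulus
    strength by default.
    """
    t = default_grid() if times is None else np.asarray(times, dtype=float)
    ai, ea = standard_processes(rat, trial_index, strength=strength)
    g = race_density(t, ai, ea, delta=delta)
    if include_contaminants:
        g = contaminated_density(g, rat.contaminant())
    g.component = "shifted_prediction"
    return g
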