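"""Shared fixtures: a reference subject in the express-response regime and
reusable simulated datasets (session-scoped; everything seeded)."""

import numpy as np
import pandas as pd
import pytest

from psiam.params import RatParams
from psiam.simulate import simulate_dataset
from psiam.synth import generate_sessions


@pytest.fixture(scope="session")
def fast_rat() -> RatParams:
    """A subject with overlapping AI/EA densities: plenty of fixation
    breaks, express (proactive) responses and reactive responses."""
    return RatParams(
        nu_a0=5.5, nu_trial=-0.002, theta_a=1.6, t_a=-0.12,
        nu_e=5.0, theta_e=0.75, t_e=0.05, z_e=0.0,
        c=0.06, d=0.6, beta=8.0,
    )


@pytest.fixture(scope="session")
def std_table() -> pd.DataFrame:
    rng = np.random.default_rng(11)
    return generate_sessions(rng, n_sessions=10, n_trials=700)


@pytest.fixture(scope="session")
def sim_outcomes(fast_rat, std_table) -> pd.DataFrame:
    """7000 simulated standard trials from the reference subject."""
    return simulate_dataset(fast_rat, std_table, dt=2e-4, rng=21)


@pytest.fixture(scope="session")
def sim_outcomes_large(fast_rat) -> pd.DataFrame:
    """2e4 simulated trials, used by the likelihood-landscape checks."""
    rng = np.random.default_rng(31)
    table = generate_sessions(rng, n_sessions=29, n_trials=700)[:20000]
    return simulate_dataset(fast_rat, table, dt=2e-4, rng=rng)
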