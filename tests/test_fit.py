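"""Likelihood construction, BIC comparison, and catch-condition refits.

The full multi-start recovery experiment lives in the acceptance suite;
here the likelihood itself is validated (landscape, FB handling,
contaminant limits) together with the cheaper fitting operations.
"""

import numpy as np
import pandas as pd
import pytest

from psiam.densities import ai_pdf, contaminant_pdf, race_density, default_grid
from psiam.fit import (
    FitFailure,
    FitResult,
    compare_bic,
    fit_mle,
    free_parameters,
    loglik_dataset,
    refit_catch,
    trial_loglik,
)
from psiam.params import AIParams, RatParams
from psiam.simulate import simulate_dataset
from psiam.trials import Trial


class TestTrialLoglik:
    def test_fixation_break_uses_ai_branch_only(self, fast_rat):
        trial = Trial(index=1, strength_signed=1.0)
        rt = -0.1
        ll = trial_loglik(fast_rat, trial, rt)
        ai = AIParams(fast_rat.nu_a0 + fast_rat.nu_trial, fast_rat.theta_a, fast_rat.t_a)
        cont = fast_rat.contaminant()
        expected = np.log(
            cont.c * contaminant_pdf(np.array([rt]), cont)[0]
            + (1 - cont.c) * ai_pdf(np.array([rt]), ai)[0]
        )
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_no_contaminants_equals_race_density(self, fast_rat):
        rat = fast_rat.replace(c=0.0)
        trial = Trial(index=1, strength_signed=0.5)
        from psiam.trials import trial_params

        ai, ea = trial_params(rat, trial)
        g = race_density(np.array([0.1499, 0.15, 0.1501]), ai, ea)
        assert trial_loglik(rat, trial, 0.15) == pytest.approx(np.log(g.pdf[1]), rel=1e-9)

    def test_outside_support_is_minus_inf(self, fast_rat):
        assert trial_loglik(fast_rat, Trial(index=1), -0.35) == -np.inf
        assert trial_loglik(fast_rat, Trial(index=1), 1.2) == -np.inf

    def test_silent_trial_uses_ai_alone(self, fast_rat):
        rat = fast_rat.replace(c=0.0)
        t = Trial(index=1, silent=True)
        ai = AIParams(rat.nu_a0 + rat.nu_trial, rat.theta_a, rat.t_a)
        assert trial_loglik(rat, t, 0.2) == pytest.approx(
            np.log(ai_pdf(np.array([0.2]), ai)[0]), rel=1e-9
        )


class TestLoglikDataset:
    def test_generating_parameters_beat_perturbations(self, fast_rat, sim_outcomes_large):
        valid = sim_outcomes_large[
            np.isfinite(sim_outcomes_large.rt_s)
            & (sim_outcomes_large.rt_s > -0.3)
            & (sim_outcomes_large.rt_s <= 1.0)
        ].reset_index(drop=True)
        ll0, _ = loglik_dataset(fast_rat, valid)
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(50):
            pert = fast_rat.replace(
                nu_a0=fast_rat.nu_a0 * rng.uniform(0.85, 1.18),
                theta_a=fast_rat.theta_a * rng.uniform(0.85, 1.18),
                nu_e=fast_rat.nu_e * rng.uniform(0.85, 1.18),
                theta_e=fast_rat.theta_e * rng.uniform(0.85, 1.18),
                t_e=float(np.clip(fast_rat.t_e + rng.uniform(-0.012, 0.012), 0.035, 0.075)),
                c=float(np.clip(fast_rat.c + rng.uniform(-0.03, 0.03), 0.0, 0.5)),
            )
            ll, _ = loglik_dataset(pert, valid)
            wins += ll < ll0
        assert wins >= 48  # allow a couple of sub-resolution perturbations

    def test_renormalized_beats_raw_for_truth(self, fast_rat, sim_outcomes_large):
        # with censoring, the truncated likelihood is the consistent one
        valid = sim_outcomes_large[
            (sim_outcomes_large.rt_s > -0.3) & (sim_outcomes_large.rt_s <= 1.0)
        ].reset_index(drop=True)
        ll_norm, _ = loglik_dataset(fast_rat, valid, renormalize=True)
        ll_raw, _ = loglik_dataset(fast_rat, valid, renormalize=False)
        assert np.isfinite(ll_norm) and np.isfinite(ll_raw)
        assert ll_norm >= ll_raw  # support mass <= 1 for every trial


class TestBic:
    def _mk(self, ll, k, n):
        return FitResult(
            params=RatParams(), loglik=ll, bic=k * np.log(n) - 2 * ll, n_trials=n,
            mode="standard", free_names=["p"] * k, starts=pd.DataFrame(),
        )

    def test_identical_fits_tie(self):
        a = self._mk(-1000.0, 10, 10_000)
        assert compare_bic(a, a) == 0.0

    def test_useless_extra_parameter_penalized_by_log_n(self):
        n = 10_000
        a = self._mk(-1000.0, 10, n)
        b = self._mk(-1000.0, 11, n)
        assert compare_bic(a, b) == pytest.approx(np.log(n))

    def test_free_parameter_counts_by_mode(self):
        assert len(free_parameters("standard")) == 10
        assert len(free_parameters("biased")) == 11
        assert len(free_parameters("reward")) == 12
        with pytest.raises(ValueError):
            free_parameters("bogus")


class TestFitGuards:
    def test_too_few_trials_rejected(self, fast_rat):
        df = pd.DataFrame(
            {"trial_index": np.arange(1, 50), "strength_signed": 1.0, "rt_s": 0.2}
        )
        with pytest.raises(FitFailure):
            fit_mle(df, n_starts=1, rng=0)


@pytest.fixture(scope="module")
def delayed_outcomes(fast_rat):
    """Delayed-stimulus condition (+150 ms) generated with an extra 30 ms
    of EA latency on top of the pure shift."""
    slow = fast_rat.replace(t_e=fast_rat.t_e + 0.030, c=0.0, nu_trial=0.0)
    df = pd.DataFrame(
        {"trial_index": np.arange(1, 6001), "strength_signed": 1.0,
         "onset_shift_s": 0.15}
    )
    return simulate_dataset(slow, df, dt=2e-4, rng=13)


class TestRefitCatch:
    def test_self_consistency_at_zero_shift(self, fast_rat, sim_outcomes):
        sub = sim_outcomes[np.abs(sim_outcomes.strength_signed) == 1.0]
        res = refit_catch(fast_rat, sub, free=("t_e",))
        assert abs(res["dt_e"]) < 0.005
        assert res["dll"] >= -1e-6

    def test_recovers_injected_latency_shift(self, fast_rat, delayed_outcomes):
        base = fast_rat.replace(c=0.0, nu_trial=0.0)
        res = refit_catch(base, delayed_outcomes, free=("t_e",))
        assert res["dt_e"] == pytest.approx(0.030, abs=0.005)

    def test_latency_refit_beats_drift_refit(self, fast_rat, delayed_outcomes):
        base = fast_rat.replace(c=0.0, nu_trial=0.0)
        res_te = refit_catch(base, delayed_outcomes, free=("t_e",))
        res_ve = refit_catch(base, delayed_outcomes, free=("nu_e",))
        assert res_te["ll_refit"] > res_ve["ll_refit"]

    def test_empty_free_set_returns_shift_likelihood_only(self, fast_rat, delayed_outcomes):
        res = refit_catch(fast_rat.replace(nu_trial=0.0), delayed_outcomes, free=())
        assert res["dll"] == 0.0 and res["dt_e"] == 0.0

    def test_rejects_unknown_free_parameter(self, fast_rat, delayed_outcomes):
        with pytest.raises(ValueError):
            refit_catch(fast_rat, delayed_outcomes, free=("theta_e",))
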