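"""Trial-level simulation: class attribution, read-out, oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psiam.densities import default_grid, race_density
from psiam.params import AIParams, ContaminantParams, EAParams, RatParams
from psiam.simulate import (
    sample_contaminant_rt,
    simulate_dataset,
    simulate_fpt_ea,
    simulate_trial,
)
from psiam.synth import generate_sessions
from psiam.trials import Trial, trial_params


def _table(n, strength=1.0, silent=False, **cols):
    df = pd.DataFrame({"trial_index": np.arange(1, n + 1), "strength_signed": strength})
    df["silent"] = silent
    for k, v in cols.items():
        df[k] = v
    return df


class TestSimulateDataset:
    def test_silent_trials_are_never_reactive(self, fast_rat):
        out = simulate_dataset(fast_rat, _table(2000, silent=True), dt=2e-4, rng=0)
        assert set(out["class"]) <= {"proactive", "FB", "contaminant", "invalid"}

    def test_all_silent_with_no_contaminants_only_proactive_or_fb(self, fast_rat):
        rat = fast_rat.replace(c=0.0)
        out = simulate_dataset(rat, _table(2000, silent=True), dt=2e-4, rng=1)
        assert set(out["class"]) <= {"proactive", "FB", "invalid"}

    def test_chance_accuracy_at_zero_strength(self, fast_rat):
        out = simulate_dataset(
            fast_rat.replace(c=0.0), _table(10_000, strength=0.0, target_side=1.0),
            dt=2e-4, rng=2,
        )
        acc = out["correct"].dropna()
        assert acc.mean() == pytest.approx(0.5, abs=0.01 + 2 / np.sqrt(len(acc)))

    def test_rt_cdf_matches_analytic_race(self, fast_rat):
        rat = fast_rat.replace(c=0.0, nu_trial=0.0)
        out = simulate_dataset(rat, _table(12_000), dt=1e-4, rng=3)
        ai, ea = trial_params(rat, Trial(index=1, strength_signed=1.0))
        grid = np.linspace(-0.3, 5.0, 10_001)
        g = race_density(grid, ai, ea)
        rts = out.loc[out["class"] != "invalid", "rt_s"].to_numpy()
        ks = stats.ks_1samp(rts, lambda x: g.interp_cdf(x) / g.cdf[-1])
        assert ks.statistic < 0.02

    def test_deterministic_under_seed(self, fast_rat):
        a = simulate_dataset(fast_rat, _table(500), dt=2e-4, rng=7)
        b = simulate_dataset(fast_rat, _table(500), dt=2e-4, rng=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_table_rejected(self, fast_rat):
        with pytest.raises(ValueError, match="empty"):
            simulate_dataset(fast_rat, _table(0))

    def test_bad_dt_rejected(self, fast_rat):
        with pytest.raises(ValueError, match="dt"):
            simulate_dataset(fast_rat, _table(10), dt=0.0)

    def test_slowing_across_blocks_with_negative_trial_slope(self):
        rat = RatParams(nu_a0=7.0, nu_trial=-0.008, theta_a=2.0, t_a=-0.1,
                        nu_e=4.0, theta_e=1.0, t_e=0.05, c=0.0)
        out = simulate_dataset(rat, _long_session(), dt=2e-4, rng=5)
        valid = out[np.isfinite(out.rt_s) & (out.rt_s <= 1.0)]
        blocks = (valid["trial_index"] - 1) // 175
        means = valid.groupby(blocks)["rt_s"].mean()
        assert means.iloc[-1] > means.iloc[0]
        assert means.is_monotonic_increasing or (np.diff(means) > 0).mean() > 0.7

    def test_proactive_share_vs_analytic(self, fast_rat):
        rat = fast_rat.replace(c=0.0, nu_trial=0.0)
        out = simulate_dataset(rat, _table(12_000), dt=2e-4, rng=6)
        ai, ea = trial_params(rat, Trial(index=1, strength_signed=1.0))
        g = race_density(default_grid(), ai, ea)
        ok = out["class"].isin(["proactive", "reactive", "FB"])
        rts = out.loc[ok, "rt_s"].to_numpy()
        proact = out.loc[ok, "class"].isin(["proactive", "FB"]).to_numpy()
        bins = np.arange(-0.3, 0.85, 0.05)
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (rts >= lo) & (rts < hi)
            if sel.sum() < 150:
                continue
            share_obs = proact[sel].mean()
            m = (g.times >= lo) & (g.times < hi) & (g.pdf > 0)
            share_pred = np.average(
                g.proactive_share[m], weights=g.pdf[m]
            )
            se = np.sqrt(share_pred * (1 - share_pred) / sel.sum()) + 1e-3
            assert abs(share_obs - share_pred) < 4 * se + 0.01

    def test_proactive_accuracy_rises_with_rt_in_express_range(self, fast_rat):
        # longer proactive RTs mean more integrated evidence
        rat = fast_rat.replace(c=0.0, nu_trial=0.0, nu_e=4.0)
        out = simulate_dataset(rat, _table(15_000, strength=0.5), dt=2e-4, rng=8)
        pro = out[(out["class"] == "proactive") & (out.rt_s > 0) & (out.rt_s < 0.12)]
        early = pro[pro.rt_s < 0.05]["correct"].mean()
        late = pro[pro.rt_s >= 0.07]["correct"].mean()
        assert late > early


def _long_session():
    return pd.DataFrame(
        {"trial_index": np.arange(1, 701).tolist() * 10, "strength_signed": 0.5}
    )


class TestSimulateTrial:
    def test_single_trial_fields(self, fast_rat):
        ai = AIParams(v_a=5.0, theta_a=1.5, t_a=-0.1)
        ea = EAParams(v_e=5.0, theta_e=0.8, t_e=0.05)
        out = simulate_trial(ai, ea, ContaminantParams(c=0.0), rng=0)
        assert out["class"] in {"proactive", "reactive", "FB", "invalid"}
        assert out["choice"] in {"left", "right", "none"}

    def test_silent_single_trial(self):
        ai = AIParams(v_a=5.0, theta_a=1.5, t_a=-0.1)
        out = simulate_trial(ai, None, rng=1)
        assert out["class"] in {"proactive", "FB", "invalid"}


class TestContaminantSampling:
    def test_sample_within_support_and_matches_cdf(self):
        cont = ContaminantParams(c=0.1, d=0.7, beta=10.0)
        x = sample_contaminant_rt(cont, 50_000, rng=0)
        assert x.min() >= cont.t_lo and x.max() <= cont.t_hi
        from psiam.densities import contaminant_cdf

        ks = stats.ks_1samp(x, lambda t: contaminant_cdf(t, cont))
        assert ks.statistic < 0.01


class TestDtConvergence:
    def test_halving_dt_leaves_rt_cdf_unchanged(self, fast_rat):
        rat = fast_rat.replace(c=0.0, nu_trial=0.0)
        a = simulate_dataset(rat, _table(6000), dt=2e-4, rng=9)
        b = simulate_dataset(rat, _table(6000), dt=1e-4, rng=10)
        ra = a.loc[a["class"] != "invalid", "rt_s"]
        rb = b.loc[b["class"] != "invalid", "rt_s"]
        ks = stats.ks_2samp(ra, rb)
        assert ks.pvalue > 0.01
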