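import numpy as np
import pandas as pd
import pytest

from streamstate import (
    BaselineOccupancy,
    DesignSpec,
    GroupTruth,
    ImmediateEffect,
    MCMCConfig,
    TreatmentOccupancy,
    TrueParams,
    fit_immediate,
    grid_posterior_oracle,
    hypothesis_check,
    load_trait_table,
    simulate_before_after,
    simulate_panel,
)
from streamstate.models import _PanelStats
from streamstate.panel import CredibleSummary

from conftest import make_control_panel


def one_group(theta, psi, n_genera, **kwargs):
    return TrueParams(groups={1: GroupTruth(theta=theta, psi=psi, n_genera=n_genera)}, **kwargs)


class TestBaseline:
    def test_matches_grid_oracle_on_single_series(self, single_series_panel):
        """With uniform priors the sampler must agree with brute-force
        quadrature of the same likelihood over the unit square."""
        oracle_theta, oracle_psi = grid_posterior_oracle([[0, 1, 1]], resolution=2001)
        model = BaselineOccupancy(
            config=MCMCConfig(seed=5), freeze_hyperparams=(1, 1, 1, 1)
        ).fit(single_series_panel)
        assert model.draws_.pooled("theta[g0]").mean() == pytest.approx(oracle_theta, abs=0.02)
        assert model.draws_.pooled("psi[g0]").mean() == pytest.approx(oracle_psi, abs=0.02)

    def test_reduces_to_beta_bernoulli_with_frozen_flat_priors(self):
        """Under the complementary link with hyperparameters frozen at (1,1)
        the genus posteriors factorize into independent conjugate
        Beta-Bernoulli problems with known means."""
        rng = np.random.default_rng(5)
        panel = make_control_panel(rng.integers(0, 2, (3, 6, 5)))
        cfg = MCMCConfig(
            n_chains=2, total_steps=4000, burn_in=1000, thin=10, seed=8, link="complementary"
        )
        model = BaselineOccupancy(config=cfg, freeze_hyperparams=(1, 1, 1, 1)).fit(panel)
        stats = _PanelStats(panel, ["C"])
        for i, g in enumerate(panel.genera):
            for stem, k, n in (
                ("theta", stats.k0[i].sum(), stats.n0[i].sum()),
                ("psi", stats.k1[i].sum(), stats.n1[i].sum()),
            ):
                draws = model.draws_.pooled(f"{stem}[{g}]")
                conjugate = (k + 1) / (n + 2)
                conj_sd = np.sqrt(conjugate * (1 - conjugate) / (n + 3))
                mc_se = draws.std() / np.sqrt(draws.size / 4)  # conservative ESS
                assert abs(draws.mean() - conjugate) < 3 * max(mc_se, conj_sd / 20)

    def test_recovers_group_means_in_synthetic_study(self, reduced_config):
        params = one_group(0.3, 0.5, 40, kappa=50.0)
        spec = DesignSpec(n_streams=30, rows=("C",), n_batteries=2)  # 60 control series
        panel, _ = simulate_panel(params, spec, rng_seed=11)
        model = BaselineOccupancy(config=reduced_config.replace(seed=1)).fit(panel)
        summ = model.group_summaries()[1]
        assert summ["theta"].mean == pytest.approx(0.3, abs=0.05)
        assert summ["psi"].mean == pytest.approx(0.5, abs=0.05)

    def test_all_zero_panel_shrinks_colonization(self, reduced_config):
        panel = make_control_panel(np.zeros((2, 30, 5), dtype=int))
        model = BaselineOccupancy(config=reduced_config.replace(seed=2)).fit(panel)
        for g in panel.genera:
            assert model.draws_.pooled(f"theta[{g}]").mean() < 0.1

    def test_rejects_treatment_series(self):
        panel = make_control_panel(np.zeros((1, 2, 3), dtype=int))
        panel.series_meta.loc[0, "frequency"] = "F1"
        with pytest.raises(ValueError, match="control"):
            BaselineOccupancy(config=MCMCConfig(total_steps=200, burn_in=100, thin=1)).fit(panel)

    def test_rejects_expected_group_without_genera(self, reduced_config, single_series_panel):
        with pytest.raises(ValueError, match="zero genera"):
            BaselineOccupancy(config=reduced_config).fit(
                single_series_panel, expected_groups=[1, 2]
            )


class TestImmediateEffect:
    cfg = MCMCConfig(n_chains=2, total_steps=1500, burn_in=500, thin=5, seed=6)

    def test_recovers_halving_effect(self):
        before, after = simulate_before_after(0.6, 0.5, 5, 200, rng_seed=2)
        model = fit_immediate(before, after, 5, np.ones(200, int), self.cfg)
        assert model.draws_.pooled("e[1]").mean() == pytest.approx(0.5, abs=0.15)

    def test_no_survivors_concentrates_effect_near_zero(self):
        before = np.clip(simulate_before_after(0.6, 1.0, 5, 20, rng_seed=3)[0], 1, 5)
        model = fit_immediate(before, np.zeros(20, int), 5, np.ones(20, int), self.cfg)
        assert model.draws_.interval("e[1]").upper < 0.5

    def test_identical_counts_cover_null_effect(self):
        before, _ = simulate_before_after(0.6, 1.0, 5, 200, rng_seed=4)
        model = fit_immediate(before, before, 5, np.ones(200, int), self.cfg)
        ci = model.draws_.interval("e[1]")
        assert ci.lower <= 1.0 <= ci.upper

    def test_effect_estimate_monotone_in_truth(self):
        means = []
        for i, e_true in enumerate([0.25, 0.5, 1.0, 2.0]):
            before, after = simulate_before_after(0.4, e_true, 5, 150, rng_seed=10 + i)
            model = fit_immediate(before, after, 5, np.ones(150, int), self.cfg)
            means.append(model.draws_.pooled("e[1]").mean())
        assert means == sorted(means)

    def test_reports_exponentiated_effect(self):
        before, after = simulate_before_after(0.6, 0.5, 5, 30, rng_seed=5)
        model = fit_immediate(before, after, 5, np.ones(30, int), self.cfg)
        e = model.draws_.pooled("e[1]")
        assert np.allclose(model.draws_.pooled("effect_exp[1]"), np.exp(e))

    def test_counts_above_n_rejected(self):
        with pytest.raises(ValueError):
            ImmediateEffect(n_trials=5).fit([6], [0], [1])


class TestTreatment:
    def test_null_deviations_covered(self, reduced_config):
        params = one_group(0.3, 0.5, 40, kappa=50.0)
        panel, _ = simulate_panel(params, DesignSpec(), rng_seed=20)
        model = TreatmentOccupancy(config=reduced_config.replace(seed=3)).fit(panel)
        for cell in model.cells_:
            ci = model.draws_.interval(f"delta[{cell},1]")
            assert ci.lower <= 1.0 <= ci.upper

    def test_abolished_persistence_detected(self, reduced_config):
        params = one_group(0.3, 0.5, 40, kappa=50.0, delta={"I2F1": {1: 1e-9}})
        panel, _ = simulate_panel(params, DesignSpec(), rng_seed=21)
        model = TreatmentOccupancy(config=reduced_config.replace(seed=4)).fit(panel)
        ci = model.draws_.interval("delta[I2F1,1]")
        assert ci.mean < 0.3
        assert ci.upper < 1.0

    def test_control_only_panel_rejected(self, reduced_config):
        panel = make_control_panel(np.zeros((1, 3, 4), dtype=int))
        with pytest.raises(ValueError, match="only control"):
            TreatmentOccupancy(config=reduced_config).fit(panel)

    def test_unknown_battery_label_rejected(self, reduced_config):
        panel = make_control_panel(np.zeros((1, 2, 3), dtype=int))
        panel.series_meta.loc[1, "frequency"] = "F1"
        panel.series_meta.loc[1, "battery"] = 3  # no third intensity exists
        with pytest.raises(ValueError, match="unknown treatment"):
            TreatmentOccupancy(config=reduced_config).fit(panel)

    def test_frozen_deviations_reproduce_baseline_draws(self):
        params = one_group(0.3, 0.5, 10, kappa=50.0)
        spec = DesignSpec(n_streams=5, rows=("C",), n_batteries=2)
        panel, _ = simulate_panel(params, spec, rng_seed=9)
        cfg = MCMCConfig(n_chains=2, total_steps=600, burn_in=200, thin=4, seed=3)
        base = BaselineOccupancy(config=cfg).fit(panel)
        frozen = TreatmentOccupancy(config=cfg, freeze_delta=True).fit(panel)
        assert set(base.draws_.draws) == set(frozen.draws_.draws)
        for name, arr in base.draws_.draws.items():
            assert np.array_equal(arr, frozen.draws_.draws[name])

    def test_conditional_mode_fixes_genus_parameters(self, reduced_config):
        params = one_group(0.3, 0.5, 8, kappa=50.0, delta={"I1F1": {1: 0.3}})
        panel, _ = simulate_panel(params, DesignSpec(), rng_seed=30)
        base = BaselineOccupancy(config=reduced_config.replace(seed=5)).fit(panel.control_only())
        cond = TreatmentOccupancy(config=reduced_config.replace(seed=6), conditional=True).fit(
            panel, baseline=base
        )
        assert all(p.startswith("delta[") for p in cond.draws_.parameters)
        ci = cond.draws_.interval("delta[I1F1,1]")
        assert ci.mean < 0.8


class TestHypothesisCheck:
    @staticmethod
    def summ(mean):
        return CredibleSummary(mean=mean, median=mean, lower=mean - 0.02, upper=mean + 0.02)

    def test_verdict_bands(self):
        table = load_trait_table()
        # group 3 hypothesis: psi low, theta high
        summaries = {
            3: {"psi": self.summ(0.2), "theta": self.summ(0.8)},  # both in band
            4: {"psi": self.summ(0.2), "theta": self.summ(0.2)},  # theta misses moderate
            5: {"psi": self.summ(0.9), "theta": self.summ(0.2)},  # both miss
        }
        verdicts = hypothesis_check(summaries, table)
        assert verdicts == {3: "supported", 4: "partial", 5: "unsupported"}

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            hypothesis_check({42: {"psi": self.summ(0.5), "theta": self.summ(0.5)}}, load_trait_table())
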