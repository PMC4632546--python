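"""Posterior predictive checking, effect tables, prediction panels, pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from allee.checking import (
    PipelineStageError,
    bayesian_p_value,
    effect_table,
    interaction_panels,
    plot_effect_table,
    plot_interaction_panels,
    run_pipeline,
)
from allee.design import FIXED_EFFECT_NAMES, build_design
from allee.mcmc import MCMCConfig, run_chains, summarize
from allee.model import PriorSpec, SIGMA2_NAMES
from .test_mcmc import bare_dataset, draws_from_array


def draws_with_linpred(eta_draws):
    d = draws_from_array(np.zeros((1, eta_draws.shape[0])))
    d.linpred = eta_draws[None, :, :]
    return d


class TestBayesianPValue:
    def test_self_consistent_data_not_flagged(self):
        # the observed counts are themselves a replicate of the first draw:
        # the discrepancy check must not signal misfit
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            N, ndraws = 60, 300
            base = rng.normal(0.3, 0.6, size=N)
            y = rng.binomial(300, 1 / (1 + np.exp(-base)))
            # posterior over each count's own rate, as the observation-level
            # overdispersion effect produces: centered at the empirical
            # logit with the binomial-information spread
            ph = (y + 0.5) / 301
            center = logit(ph)
            sd = 1.0 / np.sqrt(300 * ph * (1 - ph))
            eta = center[None, :] + sd[None, :] * rng.standard_normal((ndraws, N))
            ds = bare_dataset(y)
            res = bayesian_p_value(draws_with_linpred(eta), ds, rng=seed + 1)
            pvals.append(res.p_value)
        pvals = np.array(pvals)
        assert np.all((pvals > 0.01) & (pvals < 0.99))
        assert ((pvals > 0.2) & (pvals < 0.8)).mean() >= 0.8

    def test_gross_misfit_detected(self):
        rng = np.random.default_rng(0)
        N, ndraws = 60, 200
        eta = rng.normal(0, 0.05, size=(ndraws, N))  # fitted p ~ 0.5
        ds = bare_dataset(np.zeros(N, dtype=int))  # but every count is zero
        res = bayesian_p_value(draws_with_linpred(eta), ds, rng=1)
        assert res.p_value < 0.01

    def test_pvalue_is_tail_fraction(self):
        rng = np.random.default_rng(3)
        eta = rng.normal(0, 0.3, size=(100, 20))
        y = rng.binomial(300, 0.55, size=20)
        res = bayesian_p_value(draws_with_linpred(eta), bare_dataset(y), rng=4)
        assert res.p_value == pytest.approx(
            np.mean(res.replicated >= res.observed)
        )
        assert 0.0 <= res.p_value <= 1.0

    def test_alternative_discrepancies_available(self):
        rng = np.random.default_rng(5)
        eta = rng.normal(0, 0.2, size=(50, 15))
        y = rng.binomial(300, 0.5, size=15)
        for name in ("abs_residual", "deviance"):
            res = bayesian_p_value(
                draws_with_linpred(eta), bare_dataset(y), rng=6, discrepancy=name
            )
            assert res.discrepancy == name
            assert 0.0 <= res.p_value <= 1.0


def make_summary(entries):
    rows = []
    for name, (lo, hi) in entries.items():
        med = (lo + hi) / 2
        rows.append(
            {
                "parameter": name,
                "median": med,
                "ci_lo": lo,
                "ci_hi": hi,
                "p_positive": 1.0 if lo > 0 else (0.0 if hi < 0 else 0.6),
                "p_negative": 0.0 if lo > 0 else (1.0 if hi < 0 else 0.4),
                "rhat": 1.0,
                "ess": 1000.0,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


class TestEffectTable:
    def base_entries(self):
        entries = {name: (-0.2, 0.4) for name in FIXED_EFFECT_NAMES + SIGMA2_NAMES}
        return entries

    def test_negative_interval_flagged_with_sign_probability(self):
        entries = self.base_entries()
        entries["beta_den_x_vel"] = (-0.9, -0.1)
        table = effect_table(make_summary(entries))
        row = table.loc["beta_den_x_vel"]
        assert row.significant and row.sign == "negative" and row.p_sign == 1.0

    def test_interval_spanning_zero_not_flagged(self):
        table = effect_table(make_summary(self.base_entries()))
        assert not table.loc["beta_dep"].significant

    def test_levels_and_completeness(self):
        table = effect_table(make_summary(self.base_entries()))
        assert len(table) == 13
        assert (table.loc[["alpha_pden", "alpha_cat"], "level"] == "population").all()
        assert table.loc["beta_den", "level"] == "local"

    def test_flags_pure_function_of_summary(self):
        entries = self.base_entries()
        a = effect_table(make_summary(entries))
        b = effect_table(make_summary(entries))
        pd.testing.assert_frame_equal(a, b)


class TestInteractionPanels:
    def test_zero_draw_gives_flat_half_panels(self, small_study):
        females, pops = small_study
        ds = build_design(females, pops)
        draws = draws_from_array(np.zeros((1, 10)))
        draws.linpred = np.zeros((1, 10, ds.n_females))
        panels = interaction_panels(draws, ds, n_grid=8)
        assert set(panels) == {"vel_low", "vel_high", "dep_low", "dep_high"}
        for panel in panels.values():
            assert np.allclose(panel["median"], 0.5)

    def test_interaction_tilts_low_velocity_panel(self, small_study):
        females, pops = small_study
        ds = build_design(females, pops)
        arr = np.zeros((1, 10))
        draws = draws_from_array(arr)
        fixed = np.zeros((1, 13))
        fixed[0, FIXED_EFFECT_NAMES.index("beta_den")] = 1.0
        fixed[0, FIXED_EFFECT_NAMES.index("beta_den_x_vel")] = -1.0
        draws.params = np.concatenate([fixed, np.ones((1, 3))], axis=1)[None, :, :]
        panels = interaction_panels(draws, ds, n_grid=12)
        low, high = panels["vel_low"], panels["vel_high"]
        assert np.all(np.diff(low["median"]) > 0)
        # pointwise flatter under fast flow
        assert np.diff(high["median"]).max() < np.diff(low["median"]).min() + 1e-12

    def test_plots_written(self, tmp_path, small_study):
        females, pops = small_study
        ds = build_design(females, pops)
        draws = draws_from_array(np.random.default_rng(0).normal(size=(2, 40)))
        panels = interaction_panels(draws, ds, n_grid=6)
        plot_interaction_panels(panels, tmp_path / "panels.svg")
        table = effect_table(
            make_summary({n: (-0.2, 0.4) for n in FIXED_EFFECT_NAMES + SIGMA2_NAMES})
        )
        plot_effect_table(table, tmp_path / "effects.svg")
        assert (tmp_path / "panels.svg").stat().st_size > 0
        assert (tmp_path / "effects.svg").stat().st_size > 0


class TestPipeline:
    def test_smoke_simulate_fit_check_report(self, tmp_path):
        from allee.synthetic import SyntheticScenario

        scenario = SyntheticScenario(
            populations_2012=6,
            populations_2013=0,
            females_range_2012=(4, 10),
            total_females=40,
            seed=2,
        )
        cfg = MCMCConfig(n_iterations=2000, n_burnin=500, thin=10, n_chains=2, seed=3)
        out = run_pipeline(
            {"scenario": scenario, "mcmc": cfg, "seed": 2}, tmp_path / "run"
        )
        import json

        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["stages"] == [
            "simulate",
            "validate",
            "fit",
            "check",
            "report",
        ]
        assert manifest["n_females_usable"] == 40
        for fname in ("draws.csv", "summary.csv", "effect_table.csv", "ppc.json"):
            assert (out / fname).exists()

    def test_missing_input_fails_in_validate_stage(self, tmp_path):
        with pytest.raises(PipelineStageError, match="validate"):
            run_pipeline(
                {
                    "females": tmp_path / "nope.csv",
                    "populations": tmp_path / "nope2.csv",
                    "mcmc": MCMCConfig(
                        n_iterations=200, n_burnin=50, thin=5, n_chains=2
                    ),
                },
                tmp_path / "run2",
            )
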