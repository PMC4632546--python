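"""Study-design emulation, ground-truth recovery and the cryptic scenario."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from allee.design import FIXED_EFFECT_NAMES, build_design
from allee.synthetic import (
    CovariateTarget,
    MechanisticConfig,
    MechanisticScene,
    ScenarioConfigurationError,
    SyntheticScenario,
    cryptic_scenario,
    draw_covariates,
    make_cryptic_dataset,
    make_regression_dataset,
    simulate_outcomes_regression,
    sperm_exposure,
    simulate_outcomes_mechanistic,
)

STUDY_SEED = 1  # fixed representative seed for study-size realizations


class TestDrawCovariates:
    def test_study_shape(self):
        females, pops = draw_covariates(SyntheticScenario(seed=STUDY_SEED))
        assert len(females) == 91
        assert len(pops) == 14
        assert females["year"].nunique() == 2
        per_rep = females.groupby(["population_id", "year"]).size()
        y2012 = per_rep.xs(2012, level="year")
        y2013 = per_rep.xs(2013, level="year")
        assert y2012.between(1, 12).all() and len(y2012) == 10
        assert y2013.between(4, 20).all() and len(y2013) == 4

    def test_local_density_moments_near_study_values(self):
        females, _ = draw_covariates(SyntheticScenario(seed=STUDY_SEED))
        assert females["den"].mean() == pytest.approx(18.9, rel=0.15)
        assert females["den"].std(ddof=1) == pytest.approx(18.6, rel=0.25)

    def test_covariates_respect_published_ranges(self):
        for seed in (STUDY_SEED, 2, 3):
            females, pops = draw_covariates(SyntheticScenario(seed=seed))
            assert females["den"].between(0, 79).all()
            assert females["dep"].between(10, 62).all()
            assert females["vel"].between(0.2, 76.5).all()
            assert females["sub"].between(1.3, 3.3).all()
            assert pops["cat"].between(19.1, 252.6).all()

    def test_bed_density_is_mean_of_quadrat_densities(self):
        females, pops = draw_covariates(SyntheticScenario(seed=STUDY_SEED))
        merged = females.groupby(["population_id", "year"])["den"].mean()
        for row in pops.itertuples(index=False):
            assert row.p_den == pytest.approx(
                merged.loc[(row.population_id, row.year)]
            )

    def test_catchment_shared_across_years(self):
        _, pops = draw_covariates(SyntheticScenario(seed=STUDY_SEED))
        per_pop = pops.groupby("population_id")["cat"].nunique()
        assert (per_pop == 1).all()

    def test_same_seed_identical_output(self):
        a = draw_covariates(SyntheticScenario(seed=5))
        b = draw_covariates(SyntheticScenario(seed=5))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_infeasible_target_rejected(self):
        with pytest.raises(ScenarioConfigurationError):
            CovariateTarget(mean=100.0, sd=5.0, lo=0.0, hi=50.0)


class TestRegressionOutcomes:
    def zero_param_scenario(self, **kw):
        params = {k: 0.0 for k in SyntheticScenario().true_parameters}
        params.update(kw)
        return SyntheticScenario(true_parameters=params, seed=STUDY_SEED)

    def test_null_world_gives_even_odds(self):
        sim = make_regression_dataset(self.zero_param_scenario())
        rates = np.array([r.y for r in sim.females]) / 300
        assert rates.mean() == pytest.approx(0.5, abs=0.02)

    def test_saturating_intercept_fixes_all_counts(self):
        sim = make_regression_dataset(self.zero_param_scenario(alpha_global=20.0))
        assert all(r.y == 300 for r in sim.females)

    def test_density_velocity_interaction_shapes_terciles(self):
        # beta_den=1, beta_den_x_vel=-1: the density slope of the empirical
        # logit should be clearly positive among slow-water females and
        # near zero among fast-water females
        params = {k: 0.0 for k in SyntheticScenario().true_parameters}
        params.update({"beta_den": 1.0, "beta_den_x_vel": -1.0})
        sc = SyntheticScenario(
            populations_2012=20,
            populations_2013=0,
            females_range_2012=(200, 300),
            total_females=5000,
            true_parameters=params,
            seed=17,
        )
        rng = np.random.default_rng(17)
        females, pops = draw_covariates(sc, rng)
        y, truth = simulate_outcomes_regression(females, pops, params, rng)
        z_den = truth["spec"].transform("den", females["den"])
        z_vel = truth["spec"].transform("vel", females["vel"])
        elogit = np.log((y + 0.5) / (300 - y + 0.5))
        lo, hi = np.quantile(z_vel, [1 / 3, 2 / 3])
        slope = lambda m: np.polyfit(z_den[m], elogit[m], 1)[0]
        assert slope(z_vel <= lo) > 0.5
        assert abs(slope(z_vel >= hi)) < 0.3

    def test_maximum_likelihood_recovers_truth_without_latent_noise(self):
        # zero variance components: an independent ML logistic fit on the
        # generated design must recover the coefficients within 3 SE
        params = dict(SyntheticScenario().true_parameters)
        for k in ("sigma2_gamma", "sigma2_eps", "sigma2_omega"):
            params[k] = 0.0
        sc = SyntheticScenario(
            populations_2012=20,
            populations_2013=0,
            females_range_2012=(80, 120),
            total_females=2000,
            true_parameters=params,
            seed=23,
        )
        sim = make_regression_dataset(sc, seed=23)
        ds = build_design(sim.females, sim.populations)
        yv = ds.y.astype(float)

        def nll(b):
            eta = ds.X @ b
            return -(yv @ eta - 300 * np.logaddexp(0, eta).sum())

        def grad(b):
            eta = ds.X @ b
            return -ds.X.T @ (yv - 300 * expit(eta))

        res = minimize(nll, np.zeros(13), jac=grad, method="BFGS")
        eta = ds.X @ res.x
        w = 300 * expit(eta) * (1 - expit(eta))
        info = ds.X.T @ (ds.X * w[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        true_vec = np.array([params[k] for k in FIXED_EFFECT_NAMES])
        assert np.all(np.abs(res.x - true_vec) < 3.2 * se)

    def test_same_seed_identical_counts(self):
        a = make_regression_dataset(SyntheticScenario(seed=4))
        b = make_regression_dataset(SyntheticScenario(seed=4))
        assert [r.y for r in a.females] == [r.y for r in b.females]


class TestMechanisticScene:
    def scene(self, males, counts, females, vel=5.0, dep=20.0, **cfg):
        f = np.atleast_2d(np.asarray(females, dtype=float))
        return MechanisticScene(
            reach_length=30.0,
            male_positions=np.asarray(males, dtype=float).reshape(-1, 2),
            male_counts=np.asarray(counts, dtype=float),
            female_positions=f,
            vel=np.full(len(f), vel),
            dep=np.full(len(f), dep),
            config=MechanisticConfig(**cfg),
        )

    def test_single_male_at_zero_distance_half_saturates(self):
        sc = self.scene([(3.0, 1.0)], [1], [(3.0, 1.0)], half_saturation=1.0)
        E = sperm_exposure(sc)
        assert E[0] == pytest.approx(1.0)
        _, info = simulate_outcomes_mechanistic(sc, np.random.default_rng(0))
        assert info["p"][0] == pytest.approx(0.5)

    def test_no_males_means_no_fertilization(self):
        sc = self.scene(np.zeros((0, 2)), [], [(3.0, 1.0)])
        y, info = simulate_outcomes_mechanistic(sc, np.random.default_rng(0))
        assert info["exposure"][0] == 0.0 and info["p"][0] == 0.0 and y[0] == 0

    def test_doubling_males_increases_every_exposure(self, rng):
        males = rng.uniform(0, 30, size=(15, 2))
        counts = rng.integers(1, 6, size=15)
        females = rng.uniform(0, 30, size=(6, 2))
        base = sperm_exposure(self.scene(males, counts, females))
        doubled = sperm_exposure(self.scene(males, 2 * counts, females))
        assert np.all(doubled > base)

    def test_exposure_additive_and_label_invariant(self, rng):
        males = rng.uniform(0, 30, size=(12, 2))
        counts = rng.integers(1, 4, size=12)
        females = rng.uniform(0, 30, size=(5, 2))
        whole = sperm_exposure(self.scene(males, counts, females))
        first = sperm_exposure(self.scene(males[:7], counts[:7], females))
        second = sperm_exposure(self.scene(males[7:], counts[7:], females))
        assert np.allclose(whole, first + second)
        perm = rng.permutation(12)
        shuffled = sperm_exposure(self.scene(males[perm], counts[perm], females))
        assert np.allclose(whole, shuffled)

    def test_infinite_decay_length_homogenizes_exposure(self, rng):
        males = rng.uniform(0, 30, size=(10, 2))
        counts = rng.integers(1, 5, size=10)
        females = rng.uniform(0, 30, size=(4, 2))
        sc = self.scene(males, counts, females, lambda0=1e9)
        E = sperm_exposure(sc)
        assert np.allclose(E, counts.sum(), rtol=1e-6)

    def test_vanishing_decay_length_keeps_only_zero_distance_males(self, rng):
        females = np.array([[3.0, 1.0], [10.0, 1.0]])
        males = np.vstack([females[0], [[4.0, 1.0], [11.0, 1.0]]])
        sc = self.scene(males, [5, 3, 3], females, lambda0=1e-9)
        E = sperm_exposure(sc)
        assert E[0] == pytest.approx(5.0)  # only her own-position males remain
        assert E[1] == pytest.approx(0.0, abs=1e-12)

    def test_decay_length_increases_with_velocity_and_depth(self):
        cfg = MechanisticConfig()
        sc = self.scene([(0.0, 0.0)], [1], [(0.0, 0.0), (0.0, 0.0)])
        sc.vel = np.array([5.0, 30.0])
        sc.dep = np.array([20.0, 20.0])
        lam = sc.decay_length()
        assert lam[1] > lam[0]
        sc.vel = np.array([5.0, 5.0])
        sc.dep = np.array([20.0, 50.0])
        lam = sc.decay_length()
        assert lam[1] > lam[0]


class TestCrypticScenario:
    def test_requires_mechanistic_flavor(self):
        with pytest.raises(ScenarioConfigurationError):
            make_cryptic_dataset(SyntheticScenario(seed=1))

    def test_two_scale_contrast_in_oversampled_world(self):
        # bed-scale density tells little; quadrat-scale density in slow
        # water tells a lot -- the cryptic pattern, by construction
        sc = cryptic_scenario(
            populations_2012=30,
            populations_2013=0,
            females_range_2012=(80, 120),
            total_females=3000,
            seed=5,
        )
        sim = make_cryptic_dataset(sc)
        f = pd.DataFrame([vars(r) for r in sim.females])
        f["fert"] = f.y / 300
        beds = f.groupby("population_id").agg(
            pden=("den", "mean"), mfert=("fert", "mean")
        )
        r_bed = np.corrcoef(beds.pden, beds.mfert)[0, 1]
        slow = f[f.vel <= f.vel.quantile(0.25)]
        r_slow = np.corrcoef(slow.den, slow.fert)[0, 1]
        assert abs(r_bed) < 0.2
        assert r_slow > 0.4

    def test_truth_annotations_cover_every_female(self):
        sim = make_cryptic_dataset(cryptic_scenario(seed=STUDY_SEED))
        truth = sim.truth["per_female"]
        assert len(truth) == len(sim.females)
        assert (truth["p"].between(0, 1)).all()
        assert (truth["exposure"] >= 0).all()

    def test_same_seed_identical_dataset(self):
        a = make_cryptic_dataset(cryptic_scenario(seed=6))
        b = make_cryptic_dataset(cryptic_scenario(seed=6))
        assert [r.y for r in a.females] == [r.y for r in b.females]
        assert a.populations == b.populations
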