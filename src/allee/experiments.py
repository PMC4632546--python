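"""Reusable simulation experiments: recovery, calibration, conjugate limit.

These are the study-level computations behind the analysis scripts: fit
the hierarchical model to data whose truth is known and measure what
comes back.  Problem sizes are reduced relative to the field-scale chain
settings (shorter chains, fewer replicates) so a full experiment battery
runs on a single CPU in minutes; the methods note records the sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .checking import bayesian_p_value
from .design import Dataset, FIXED_EFFECT_NAMES, StandardizationSpec, build_design
from .mcmc import MCMCConfig, run_chains, summarize
from .model import PriorSpec
from .synthetic import (
    SyntheticScenario,
    cryptic_scenario,
    make_cryptic_dataset,
    make_regression_dataset,
)

__all__ = [
    "RECOVERY_CONFIG",
    "REDUCED_CONFIG",
    "recovery_scenario",
    "run_recovery",
    "run_pvalue_calibration",
    "run_cryptic_fit",
    "single_proportion_dataset",
    "run_conjugate_check",
]

#: Reduced chain settings for recovery experiments: a quarter of the
#: field-scale run, long enough for R-hat near 1 on this problem size.
RECOVERY_CONFIG = MCMCConfig(
    n_iterations=20_000, n_burnin=5_000, thin=10, n_chains=3
)

#: Short settings for many-replicate calibration batteries.
REDUCED_CONFIG = MCMCConfig(n_iterations=6_000, n_burnin=1_500, thin=5, n_chains=3)


def recovery_scenario(seed: int) -> SyntheticScenario:
    """Eight beds, 300 females: a mid-size design for parameter recovery."""
    return SyntheticScenario(
        populations_2012=8,
        populations_2013=0,
        females_range_2012=(20, 55),
        total_females=300,
        seed=seed,
    )


def run_recovery(seed: int, config: MCMCConfig = RECOVERY_CONFIG) -> dict:
    """Simulate known-truth data, fit, and score convergence and coverage.

    Returns the per-fixed-effect coverage indicators, the maximum split
    R-hat over the 13 fixed effects, and the posterior summary.
    """
    sim = make_regression_dataset(recovery_scenario(seed))
    ds = build_design(sim.females, sim.populations)
    cfg = MCMCConfig(
        n_iterations=config.n_iterations,
        n_burnin=config.n_burnin,
        thin=config.thin,
        n_chains=config.n_chains,
        seed=seed + 10_000,
    )
    summary = summarize(run_chains(ds, PriorSpec(), cfg))
    truth = {**sim.truth["fixed"], **sim.truth["sigma2"]}
    fixed = summary.loc[FIXED_EFFECT_NAMES].copy()
    fixed["true"] = [truth[k] for k in fixed.index]
    fixed["covered"] = (fixed.ci_lo <= fixed.true) & (fixed.true <= fixed.ci_hi)
    return {
        "summary": fixed,
        "max_rhat": float(fixed.rhat.max()),
        "n_covered": int(fixed.covered.sum()),
    }


def run_pvalue_calibration(
    n_replicates: int = 20,
    seed: int = 0,
    config: MCMCConfig = REDUCED_CONFIG,
) -> pd.DataFrame:
    """Simulate-fit replicates of the study design under the model itself.

    For correctly specified data the posterior predictive p-value should
    land well inside (0, 1), and the 95% intervals for the local-density
    effect and its velocity interaction should cover their true values at
    roughly nominal rate.
    """
    rows = []
    for r in range(n_replicates):
        rep_seed = seed + 1000 * (r + 1)
        sim = make_regression_dataset(SyntheticScenario(seed=rep_seed))
        ds = build_design(sim.females, sim.populations)
        cfg = MCMCConfig(
            n_iterations=config.n_iterations,
            n_burnin=config.n_burnin,
            thin=config.thin,
            n_chains=config.n_chains,
            seed=rep_seed + 1,
        )
        draws = run_chains(ds, PriorSpec(), cfg)
        ppc = bayesian_p_value(draws, ds, rng=rep_seed + 2)
        summary = summarize(draws)
        truth = sim.truth["fixed"]
        row = {"replicate": r, "p_value": ppc.p_value}
        for name in ("beta_den", "beta_den_x_vel"):
            lo, hi = summary.loc[name, ["ci_lo", "ci_hi"]]
            row[f"{name}_covered"] = bool(lo <= truth[name] <= hi)
        rows.append(row)
    return pd.DataFrame(rows)


def run_cryptic_fit(seed: int = 1, config: MCMCConfig = RECOVERY_CONFIG) -> dict:
    """Fit the hierarchical model to one study-size mechanistic dataset.

    The qualitative two-scale contrast is scored: sign probability of the
    local density effect and the density x velocity interaction, and
    whether the bed-scale density coefficient's interval includes zero.
    """
    sim = make_cryptic_dataset(cryptic_scenario(seed=seed))
    ds = build_design(sim.females, sim.populations)
    cfg = MCMCConfig(
        n_iterations=config.n_iterations,
        n_burnin=config.n_burnin,
        thin=config.thin,
        n_chains=config.n_chains,
        seed=seed + 20_000,
    )
    draws = run_chains(ds, PriorSpec(), cfg)
    summary = summarize(draws)
    return {
        "summary": summary,
        "draws": draws,
        "dataset": ds,
        "p_local_density_positive": float(summary.loc["beta_den", "p_positive"]),
        "p_density_velocity_negative": float(
            summary.loc["beta_den_x_vel", "p_negative"]
        ),
        "bed_density_ci": (
            float(summary.loc["alpha_pden", "ci_lo"]),
            float(summary.loc["alpha_pden", "ci_hi"]),
        ),
        "max_rhat_fixed": float(summary.loc[FIXED_EFFECT_NAMES].rhat.max()),
    }


def single_proportion_dataset(y: int, n: int = 300) -> Dataset:
    """Covariate-free, latent-free reduction: one female, intercept only."""
    X = np.zeros((1, len(FIXED_EFFECT_NAMES)))
    X[0, 0] = 1.0
    return Dataset(
        y=np.array([y], dtype=np.int64),
        n=n,
        X=X,
        date_idx=np.zeros(1, dtype=np.intp),
        pop_idx=np.zeros(1, dtype=np.intp),
        date_labels=[],
        pop_labels=[],
        spec=StandardizationSpec(means={"den": 0.0}, sds={"den": 1.0}),
        natural=pd.DataFrame({"den": [0.0]}),
        overdispersion=False,
    )


def run_conjugate_check(y: int = 210, n: int = 300, seed: int = 7) -> dict:
    """Sampler vs closed form on the single-proportion reduction.

    With every covariate dropped and no latent effects, the vague normal
    prior on the logit is locally flat and its Jacobian onto the rate
    scale is 1/(p(1-p)), so the posterior of p is Beta(y, n-y) to high
    accuracy; the sampled 2.5/50/97.5 percentiles are compared against it.
    """
    ds = single_proportion_dataset(y, n)
    cfg = MCMCConfig(
        n_iterations=30_000, n_burnin=5_000, thin=5, n_chains=2, seed=seed
    )
    draws = run_chains(ds, PriorSpec(), cfg)
    p_draws = expit(draws.pooled("alpha_global"))
    oracle = beta_dist(y, n - y)
    qs = (0.025, 0.5, 0.975)
    sampled = {q: float(np.quantile(p_draws, q)) for q in qs}
    analytic = {q: float(oracle.ppf(q)) for q in qs}
    return {
        "sampled": sampled,
        "analytic": analytic,
        "max_abs_error": max(abs(sampled[q] - analytic[q]) for q in qs),
    }
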