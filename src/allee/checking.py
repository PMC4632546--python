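"""Posterior predictive checking, effect tables, prediction panels, pipeline.

The goodness-of-fit check is a posterior predictive Bayesian p-value:
for every kept draw, a discrepancy is computed for the observed counts
and for counts replicated from the same draw, and the p-value is the
fraction of draws where the replicated discrepancy is at least the
observed one.  Values near 0.5 indicate adequate fit; values piling at
0 or 1 indicate misfit.  The default discrepancy is the Pearson
chi-square for binomial counts; absolute-residual and deviance
alternatives are provided.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Dataset, FIXED_EFFECT_NAMES
from .mcmc import MCMCConfig, PosteriorDraws, run_chains, summarize
from .model import PriorSpec, predict_fertilization_curve

__all__ = [
    "PosteriorPredictiveResult",
    "bayesian_p_value",
    "effect_table",
    "interaction_panels",
    "plot_effect_table",
    "plot_interaction_panels",
    "run_pipeline",
    "PipelineStageError",
]

_P_CLIP = 1e-12


def _expit(x):
    from scipy.special import expit

    return expit(x)


def _pearson_chi2(y, n, p):
    return np.sum((y - n * p) ** 2 / (n * p * (1.0 - p)), axis=-1)


def _abs_residual(y, n, p):
    return np.sum(np.abs(y - n * p), axis=-1)


def _deviance(y, n, p):
    yn = np.clip(y / n, _P_CLIP, 1 - _P_CLIP)
    return 2.0 * np.sum(
        n * (yn * np.log(yn / p) + (1 - yn) * np.log((1 - yn) / (1 - p))), axis=-1
    )


DISCREPANCIES = {
    "pearson_chi2": _pearson_chi2,
    "abs_residual": _abs_residual,
    "deviance": _deviance,
}


@dataclass
class PosteriorPredictiveResult:
    """Bayesian p-value with its per-draw discrepancy trace."""

    p_value: float
    discrepancy: str
    observed: np.ndarray  # discrepancy of the observed data, per draw
    replicated: np.ndarray  # discrepancy of replicated data, per draw
    n_clipped: int  # draws where a fitted p touched the numerical boundary


def bayesian_p_value(
    draws: PosteriorDraws,
    dataset: Dataset,
    rng: np.random.Generator | int = 0,
    discrepancy: str = "pearson_chi2",
) -> PosteriorPredictiveResult:
    """Posterior predictive p-value over the kept draws.

    Uses the stored per-female linear predictors, so the replicated data
    inherit the fitted latent effects (date, population, overdispersion)
    exactly as the observed data do.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    T = DISCREPANCIES[discrepancy]
    eta = draws.linpred_pooled()
    p = _expit(eta)
    clipped = np.sum(np.any((p <= _P_CLIP) | (p >= 1 - _P_CLIP), axis=1))
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    n = dataset.n
    t_obs = T(dataset.y[None, :], n, p)
    y_rep = rng.binomial(n, p)
    t_rep = T(y_rep, n, p)
    return PosteriorPredictiveResult(
        p_value=float(np.mean(t_rep >= t_obs)),
        discrepancy=discrepancy,
        observed=t_obs,
        replicated=t_rep,
        n_clipped=int(clipped),
    )


def effect_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect summary table in presentation order.

    One row per coefficient (population-level terms first, then the nine
    quadrat-level terms) with median, 95% credible interval, the
    probability of the dominant sign, and a flag marking intervals that
    exclude zero.
    """
    order = [
        "alpha_pden",
        "alpha_cat",
        "alpha_pden_x_cat",
        "beta_den",
        "beta_vel",
        "beta_dep",
        "beta_sub",
        "beta_den_x_vel",
        "beta_den_x_dep",
        "beta_den_x_sub",
        "beta_loc",
        "beta_shell",
        "alpha_global",
    ]
    rows = summary.loc[[k for k in order if k in summary.index]].copy()
    rows["level"] = [
        "population" if k.startswith("alpha") and k != "alpha_global" else
        ("intercept" if k == "alpha_global" else "local")
        for k in rows.index
    ]
    rows["p_sign"] = np.maximum(rows["p_positive"], rows["p_negative"])
    rows["sign"] = np.where(rows["p_positive"] >= 0.5, "positive", "negative")
    return rows[
        ["level", "median", "ci_lo", "ci_hi", "p_positive", "p_negative",
         "p_sign", "sign", "significant"]
    ]


def interaction_panels(
    draws: PosteriorDraws,
    dataset: Dataset,
    n_grid: int = 50,
    percentiles: tuple[float, float] = (25.0, 75.0),
) -> dict[str, pd.DataFrame]:
    """Predicted fertilization vs local density, conditioned on flow.

    Four panels: density against fertilization at the dataset's empirical
    25th and 75th percentile of current velocity, and likewise of water
    depth.  Other covariates sit at their means (standardized zero) and
    latent effects at zero, so the curves describe population-average
    expectations.  Axes are in natural units.
    """
    nat = dataset.natural
    den_grid = np.linspace(nat["den"].min(), nat["den"].max(), n_grid)
    fixed = draws.fixed_pooled()
    panels = {}
    for var in ("vel", "dep"):
        lo_v, hi_v = np.percentile(nat[var].to_numpy(dtype=float), percentiles)
        for tag, value in (("low", lo_v), ("high", hi_v)):
            kwargs = {var: float(value)}
            curve = predict_fertilization_curve(
                fixed, dataset.spec, den_grid, **kwargs
            )
            panels[f"{var}_{tag}"] = pd.DataFrame(
                {
                    "den": curve["den"],
                    "median": curve["median"],
                    "lo": curve["lo"],
                    "hi": curve["hi"],
                    "conditioning_value": float(value),
                }
            )
    return panels


def plot_effect_table(table: pd.DataFrame, path: str | Path) -> None:
    """Caterpillar plot of the fixed effects (medians and 95% intervals)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = table[table.index != "alpha_global"]
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(rows) + 1.5))
    ypos = np.arange(len(rows))[::-1]
    colors = ["crimson" if s else "grey" for s in rows["significant"]]
    ax.hlines(ypos, rows["ci_lo"], rows["ci_hi"], color=colors, lw=2)
    ax.plot(rows["median"], ypos, "o", color="black", ms=4)
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_yticks(ypos)
    ax.set_yticklabels(rows.index)
    ax.set_xlabel("standardized effect (logit scale)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_interaction_panels(panels: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Four-panel prediction figure: density effect under contrasting flow."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharey=True)
    labels = {"vel": "current velocity (cm/s)", "dep": "water depth (cm)"}
    for ax, (key, panel) in zip(axes.ravel(), sorted(panels.items())):
        var, tag = key.split("_")
        ax.fill_between(panel["den"], panel["lo"], panel["hi"], alpha=0.3)
        ax.plot(panel["den"], panel["median"], lw=2)
        ax.set_title(f"{labels[var]} = {panel['conditioning_value'].iloc[0]:.1f} ({tag})")
        ax.set_xlabel("local conspecific density (ind./0.25 m$^2$)")
        ax.set_ylim(0, 1)
    for ax in axes[:, 0]:
        ax.set_ylabel("fertilization rate")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Validate -> (simulate) -> fit -> check -> report, with a manifest.

    ``config`` keys: either ``scenario`` (a SyntheticScenario for
    simulation) or ``females``/``populations`` (paths to CSV tables);
    ``mcmc`` (an MCMCConfig) and optional ``seed``.  Outputs land under
    ``out_dir``; the manifest records the stages, config and file hashes.
    Partial outputs are retained when a stage fails.
    """
    from . import io as allee_io
    from .design import build_design, correlation_screen, standardize
    from .records import filter_usable

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": {}, "outputs": {}}
    seed = int(config.get("seed", 0))
    mcmc_config: MCMCConfig = config.get("mcmc", MCMCConfig())
    manifest["config"] = {
        "seed": seed,
        "mcmc": {
            "n_iterations": mcmc_config.n_iterations,
            "n_burnin": mcmc_config.n_burnin,
            "thin": mcmc_config.thin,
            "n_chains": mcmc_config.n_chains,
            "seed": mcmc_config.seed,
        },
    }

    stage = "validate"
    try:
        if "scenario" in config:
            stage = "simulate"
            from .synthetic import make_cryptic_dataset, make_regression_dataset

            scenario = config["scenario"]
            maker = (
                make_cryptic_dataset
                if scenario.scenario_flavor == "mechanistic"
                else make_regression_dataset
            )
            sim = maker(scenario, seed)
            females, populations = sim.females, sim.populations
            allee_io.write_females(females, out / "females.csv")
            allee_io.write_populations(populations, out / "pops.csv")
            manifest["stages"].append("simulate")
            stage = "validate"
        else:
            females = allee_io.read_females(Path(config["females"]))
            populations = allee_io.read_populations(Path(config["populations"]))

        usable = filter_usable(females)
        z, spec = standardize(usable, populations)
        corr, corr_ok = correlation_screen(z)
        allee_io.write_standardization(spec, out / "standardization.json")
        corr.to_csv(out / "correlation_screen.csv")
        manifest["stages"].append("validate")
        manifest["n_females_usable"] = len(usable)
        manifest["correlation_screen_pass"] = corr_ok

        stage = "fit"
        dataset = build_design(usable, populations)
        draws = run_chains(dataset, PriorSpec(), mcmc_config)
        draws.to_frame().to_csv(out / "draws.csv", index=False)
        summary = summarize(draws)
        summary.to_csv(out / "summary.csv")
        (out / "sampler_log.json").write_text(json.dumps(draws.sampler_log, indent=2))
        manifest["stages"].append("fit")

        stage = "check"
        ppc = bayesian_p_value(draws, dataset, rng=seed + 1)
        (out / "ppc.json").write_text(
            json.dumps(
                {
                    "bayesian_p_value": ppc.p_value,
                    "discrepancy": ppc.discrepancy,
                    "n_clipped": ppc.n_clipped,
                },
                indent=2,
            )
        )
        manifest["stages"].append("check")
        manifest["bayesian_p_value"] = ppc.p_value

        stage = "report"
        table = effect_table(summary)
        table.to_csv(out / "effect_table.csv")
        panels = interaction_panels(draws, dataset)
        for key, panel in panels.items():
            panel.to_csv(out / f"panel_{key}.csv", index=False)
        plot_effect_table(table, out / "effect_table.svg")
        plot_interaction_panels(panels, out / "interaction_panels.svg")
        manifest["stages"].append("report")
    except Exception as exc:  # annotate failures with the stage name
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineStageError(f"{stage}: {exc}") from exc

    manifest["outputs"] = {
        f.name: _hash_file(f) for f in sorted(out.iterdir()) if f.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
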