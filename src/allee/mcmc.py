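"""Adaptive Metropolis-within-Gibbs sampling for the hierarchical model.

The sampler mirrors BUGS-style componentwise updating: every scalar
(fixed effect, variance component, latent effect) gets a random-walk
proposal whose step size is tuned toward ~44% acceptance during burn-in
only, then frozen.  Latent effects touching disjoint likelihood rows
(the per-female overdispersion terms, the date effects, the population
intercepts) are proposed and accepted element-wise in vectorized blocks,
which is equivalent to a componentwise scan.  Because a hierarchical
intercept trades off against the mean of each latent block along a
likelihood-flat ridge, the scan also includes translation moves
(alpha_global + delta, block - delta) accepted on the prior ratio alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from math import exp as mexp, log as mlog

from .design import Dataset, FIXED_EFFECT_NAMES
from .model import ModelParameters, PriorSpec, SIGMA2_NAMES, log_posterior

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "InitializationError",
    "run_chains",
    "rhat",
    "summarize",
]

PARAM_NAMES = FIXED_EFFECT_NAMES + SIGMA2_NAMES
_BLOCKS = ("gamma", "eps", "omega")


class InitializationError(RuntimeError):
    """No finite-log-posterior starting point found."""


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings; defaults follow the study's reported run lengths."""

    n_iterations: int = 100_000
    n_burnin: int = 20_000
    thin: int = 20
    n_chains: int = 3
    seed: int = 0
    target_accept: float = 0.44
    init_scale: float = 2.5
    init_retries: int = 100
    store_linpred: bool = True
    store_latents: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin >= 1 and n_chains >= 1 required")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Kept draws of the 13 fixed effects and 3 variance components.

    ``params`` is (n_chains, n_kept, 16); ``linpred`` optionally stores the
    per-female logit-scale predictor for each kept draw, enabling posterior
    predictive checks without re-assembling latent effects.  Latent effects
    are summarized (posterior mean and sd per latent) unless full storage
    was requested.
    """

    params: np.ndarray
    names: list[str]
    linpred: np.ndarray | None
    latent_summary: pd.DataFrame
    latent_draws: dict[str, np.ndarray] | None
    sampler_log: dict
    config: MCMCConfig

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    def by_chain(self, name: str) -> np.ndarray:
        return self.params[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.by_chain(name).reshape(-1)

    def fixed_pooled(self) -> np.ndarray:
        """(n_total_draws, 13) pooled fixed-effect draws."""
        return self.params[:, :, : len(FIXED_EFFECT_NAMES)].reshape(
            -1, len(FIXED_EFFECT_NAMES)
        )

    def linpred_pooled(self) -> np.ndarray:
        if self.linpred is None:
            raise ValueError("linear predictors were not stored")
        return self.linpred.reshape(-1, self.linpred.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draw table: chain, iteration, parameter, value."""
        nc, nk, npar = self.params.shape
        chain = np.repeat(np.arange(nc), nk * npar)
        iteration = np.tile(np.repeat(np.arange(nk), npar), nc)
        parameter = np.tile(np.array(self.names, dtype=object), nc * nk)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "parameter": parameter,
                "value": self.params.reshape(-1),
            }
        )


def _row_loglik(y: np.ndarray, n: int, eta: np.ndarray) -> np.ndarray:
    # binomial log-likelihood per row without the eta-free coefficient term
    return y * eta - n * np.logaddexp(0.0, eta)


def _reflect(x: float, upper: float) -> float:
    # fold a real into [0, upper] by reflection at both bounds
    period = 2.0 * upper
    x = abs(x) % period
    return period - x if x > upper else x


def _init_state(
    dataset: Dataset, prior: PriorSpec, config: MCMCConfig, rng: np.random.Generator
) -> ModelParameters:
    for _ in range(config.init_retries):
        params = ModelParameters(
            fixed=config.init_scale * rng.standard_normal(len(FIXED_EFFECT_NAMES)),
            sigma2=rng.uniform(0.2, 5.0, 3),
            gamma=np.zeros(dataset.n_dates),
            eps=np.zeros(dataset.n_females),
            omega=np.zeros(dataset.n_pops),
        )
        n_eps = dataset.n_females if dataset.overdispersion else 0
        params.gamma = np.sqrt(params.sigma2[0]) * rng.standard_normal(dataset.n_dates)
        params.eps = np.sqrt(params.sigma2[1]) * rng.standard_normal(n_eps)
        params.omega = np.sqrt(params.sigma2[2]) * rng.standard_normal(dataset.n_pops)
        if np.isfinite(log_posterior(params, dataset, prior)):
            return params
    raise InitializationError(
        f"no finite log-posterior in {config.init_retries} initialization attempts"
    )


def _run_single_chain(
    dataset: Dataset,
    prior: PriorSpec,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> dict:
    y = dataset.y.astype(float)
    n = dataset.n
    X = dataset.X
    date_idx, pop_idx = dataset.date_idx, dataset.pop_idx
    N, D, P = dataset.n_females, dataset.n_dates, dataset.n_pops
    coef_var = prior.coef_variance
    var_upper = prior.var_upper

    state = _init_state(dataset, prior, config, rng)
    fixed, sigma2 = state.fixed, state.sigma2
    blocks = {"gamma": state.gamma, "eps": state.eps, "omega": state.omega}
    block_idx = {"gamma": date_idx, "eps": None, "omega": pop_idx}
    block_sigma = {"gamma": 0, "eps": 1, "omega": 2}

    eta = (
        X @ fixed
        + (blocks["gamma"][date_idx] if D else 0.0)
        + (blocks["eps"] if blocks["eps"].size else 0.0)
        + (blocks["omega"][pop_idx] if P else 0.0)
    )
    # maintained state: per-row softplus of eta and its total; the binomial
    # log-likelihood delta for any proposal follows from these and y
    rowsp = np.logaddexp(0.0, eta)
    sp_sum = float(rowsp.sum())
    Xcols = [np.ascontiguousarray(X[:, m]) for m in range(X.shape[1])]
    yX = X.T @ y  # y' X, one dot per fixed effect

    # population-level design (constant within a population replicate):
    # intercept, P_DEN, CAT, P_DEN*CAT columns evaluated once per replicate
    n_pop_terms = 4
    Xp = np.zeros((P, n_pop_terms))
    for j in range(P):
        rows = np.flatnonzero(pop_idx == j)
        if rows.size:
            Xp[j] = X[rows[0], :n_pop_terms]
    # date/population pairs whose groups coincide exactly (a bed sampled on
    # its own date): the gamma and omega effects are then interchangeable
    pairs = []
    for j in range(P):
        dates_j = np.unique(date_idx[pop_idx == j])
        if dates_j.size == 1:
            k = int(dates_j[0])
            if np.all(pop_idx[date_idx == k] == j):
                pairs.append((j, k))

    n_fixed = len(FIXED_EFFECT_NAMES)
    # log step sizes, adapted during burn-in only
    ls_fixed = np.full(len(FIXED_EFFECT_NAMES), np.log(0.1))
    ls_block = {b: np.full(len(blocks[b]), np.log(0.5)) for b in _BLOCKS}
    ls_sigma2 = np.full(3, np.log(1.0))
    ls_shift = np.full(2, np.log(0.5))  # alpha_global vs gamma, vs eps
    ls_swap = np.full(n_pop_terms, np.log(0.5))  # pop-level coefs vs omega
    ls_pair = np.full(max(len(pairs), 1), np.log(0.5))
    # joint fixed-effect proposal: covariance learned during burn-in
    # (adaptive Metropolis), scale factor tuned toward ~23% acceptance
    ls_joint = 0.0
    fm_count, fm_mean = 0, np.zeros(n_fixed)
    fm_M2 = np.zeros((n_fixed, n_fixed))
    joint_chol: np.ndarray | None = None
    LS_LO, LS_HI = np.log(1e-5), np.log(50.0)
    target = config.target_accept

    n_kept = config.n_kept
    params_out = np.empty((n_kept, len(PARAM_NAMES)))
    linpred_out = np.empty((n_kept, N)) if config.store_linpred else None
    latent_out = (
        {b: np.empty((n_kept, len(blocks[b]))) for b in _BLOCKS}
        if config.store_latents
        else None
    )
    latent_sum = {b: np.zeros(len(blocks[b])) for b in _BLOCKS}
    latent_sumsq = {b: np.zeros(len(blocks[b])) for b in _BLOCKS}
    accept_count = {"fixed": 0.0, "sigma2": 0.0, "shift": 0.0, "joint": 0.0}
    accept_count.update({b: 0.0 for b in _BLOCKS})
    post_burnin_scans = 0
    kept = 0
    ls_at_freeze: dict | None = None

    for t in range(config.n_iterations):
        adapting = t < config.n_burnin
        gain = 2.0 / (t + 20.0) ** 0.6 if adapting else 0.0
        tracking = not adapting

        # --- fixed effects, one scalar at a time ---
        for m in range(n_fixed):
            d = mexp(ls_fixed[m]) * rng.standard_normal()
            eta_new = eta + d * Xcols[m]
            rowsp_new = np.logaddexp(0.0, eta_new)
            sp_new = float(rowsp_new.sum())
            new_val = fixed[m] + d
            logr = (
                d * yX[m]
                - n * (sp_new - sp_sum)
                + (fixed[m] * fixed[m] - new_val * new_val) / (2.0 * coef_var)
            )
            if mlog(rng.random()) < logr:
                fixed[m] = new_val
                eta, rowsp, sp_sum = eta_new, rowsp_new, sp_new
                if tracking:
                    accept_count["fixed"] += 1.0
            if adapting:
                a = mexp(min(0.0, logr))
                ls_fixed[m] = min(max(ls_fixed[m] + gain * (a - target), LS_LO), LS_HI)

        # --- joint fixed-effect move along the learned posterior covariance ---
        if adapting:
            fm_count += 1
            delta = fixed - fm_mean
            fm_mean += delta / fm_count
            fm_M2 += np.outer(delta, fixed - fm_mean)
            if fm_count >= 300 and fm_count % 100 == 0:
                cov = fm_M2 / (fm_count - 1)
                joint_chol = np.linalg.cholesky(
                    (2.38**2 / n_fixed) * cov + 1e-10 * np.eye(n_fixed)
                )
        if joint_chol is not None:
            d = mexp(ls_joint) * (joint_chol @ rng.standard_normal(n_fixed))
            new_fixed = fixed + d
            eta_new = eta + X @ d
            rowsp_new = np.logaddexp(0.0, eta_new)
            sp_new = float(rowsp_new.sum())
            logr = (
                float(yX @ d)
                - n * (sp_new - sp_sum)
                + (float(fixed @ fixed) - float(new_fixed @ new_fixed))
                / (2.0 * coef_var)
            )
            if mlog(rng.random()) < logr:
                fixed[:] = new_fixed
                eta, rowsp, sp_sum = eta_new, rowsp_new, sp_new
                if tracking:
                    accept_count["joint"] += 1.0
            if adapting:
                a = mexp(min(0.0, logr))
                ls_joint = min(max(ls_joint + gain * (a - 0.234), LS_LO), LS_HI)

        # --- latent blocks: element-wise proposals over disjoint rows ---
        for b in _BLOCKS:
            vec = blocks[b]
            K = len(vec)
            if K == 0:
                continue
            s2 = sigma2[block_sigma[b]]
            d = np.exp(ls_block[b]) * rng.standard_normal(K)
            idx = block_idx[b]
            d_rows = d if idx is None else d[idx]
            eta_new = eta + d_rows
            rowsp_new = np.logaddexp(0.0, eta_new)
            dll_rows = y * d_rows - n * (rowsp_new - rowsp)
            dll = dll_rows if idx is None else np.bincount(
                idx, weights=dll_rows, minlength=K
            )
            new_vec = vec + d
            logr = dll + (vec * vec - new_vec * new_vec) / (2.0 * s2)
            acc = np.log(rng.random(K)) < logr
            row_acc = acc if idx is None else acc[idx]
            vec[acc] = new_vec[acc]
            eta[row_acc] = eta_new[row_acc]
            rowsp[row_acc] = rowsp_new[row_acc]
            sp_sum = float(rowsp.sum())
            if tracking:
                accept_count[b] += acc.mean()
            if adapting:
                a = np.exp(np.minimum(0.0, logr))
                ls_block[b] = np.clip(ls_block[b] + gain * (a - target), LS_LO, LS_HI)

        # --- variance components on the sigma^2 scale, reflected at (0, upper) ---
        for k in range(3):
            vec = blocks[_BLOCKS[k]]
            K = len(vec)
            cur = sigma2[k]
            prop = _reflect(cur + mexp(ls_sigma2[k]) * rng.standard_normal(), var_upper)
            if prop <= 0.0:
                a = 0.0
            else:
                ss = float(vec @ vec)
                logr = -0.5 * K * (mlog(prop) - mlog(cur)) - 0.5 * ss * (
                    1.0 / prop - 1.0 / cur
                )
                a = mexp(min(0.0, logr))
                if mlog(rng.random()) < logr:
                    sigma2[k] = prop
                    if tracking:
                        accept_count["sigma2"] += 1.0 / 3.0
            if adapting:
                ls_sigma2[k] = min(max(ls_sigma2[k] + gain * (a - target), LS_LO), LS_HI)

        # --- likelihood-invariant moves along posterior ridges ---
        # (a) global intercept vs the mean of the gamma / eps blocks
        n_ridge = 0
        n_shift_accept = 0.0
        for k, b in enumerate(("gamma", "eps")):
            vec = blocks[b]
            if len(vec) == 0:
                continue
            n_ridge += 1
            s2 = sigma2[block_sigma[b]]
            d = mexp(ls_shift[k]) * rng.standard_normal()
            new_alpha = fixed[0] + d
            new_vec = vec - d
            logr = (fixed[0] ** 2 - new_alpha**2) / (2.0 * coef_var) + (
                float(vec @ vec) - float(new_vec @ new_vec)
            ) / (2.0 * s2)
            if mlog(rng.random()) < logr:
                fixed[0] = new_alpha
                vec -= d  # eta unchanged: every row carries exactly one block term
                n_shift_accept += 1.0
            if adapting:
                a = mexp(min(0.0, logr))
                ls_shift[k] = min(max(ls_shift[k] + gain * (a - target), LS_LO), LS_HI)

        # (b) population-level coefficients vs omega along covariate directions:
        # rows see Xp[pop] @ fixed[:4] + omega[pop], so (fixed[k] + d,
        # omega - d * Xp[:, k]) leaves every linear predictor unchanged
        if P:
            om = blocks["omega"]
            s2_om = sigma2[2]
            for k in range(n_pop_terms):
                n_ridge += 1
                d = mexp(ls_swap[k]) * rng.standard_normal()
                new_fk = fixed[k] + d
                new_om = om - d * Xp[:, k]
                logr = (fixed[k] ** 2 - new_fk**2) / (2.0 * coef_var) + (
                    float(om @ om) - float(new_om @ new_om)
                ) / (2.0 * s2_om)
                if mlog(rng.random()) < logr:
                    fixed[k] = new_fk
                    om[:] = new_om
                    n_shift_accept += 1.0
                if adapting:
                    a = mexp(min(0.0, logr))
                    ls_swap[k] = min(max(ls_swap[k] + gain * (a - target), LS_LO), LS_HI)

        # (c) gamma vs omega for beds sampled on their own date, where both
        # effects enter exactly the same rows and only their sum is identified
        if pairs:
            gam, om = blocks["gamma"], blocks["omega"]
            s2_g, s2_om = sigma2[0], sigma2[2]
            for ip, (j, k) in enumerate(pairs):
                n_ridge += 1
                d = mexp(ls_pair[ip]) * rng.standard_normal()
                gk, oj = gam[k], om[j]
                logr = (gk * gk - (gk - d) ** 2) / (2.0 * s2_g) + (
                    oj * oj - (oj + d) ** 2
                ) / (2.0 * s2_om)
                if mlog(rng.random()) < logr:
                    gam[k] = gk - d
                    om[j] = oj + d
                    n_shift_accept += 1.0
                if adapting:
                    a = mexp(min(0.0, logr))
                    ls_pair[ip] = min(max(ls_pair[ip] + gain * (a - target), LS_LO), LS_HI)

        if tracking and n_ridge:
            accept_count["shift"] += n_shift_accept / n_ridge

        if t == config.n_burnin - 1 or (config.n_burnin == 0 and t == 0):
            ls_at_freeze = {
                "fixed": ls_fixed.copy(),
                "sigma2": ls_sigma2.copy(),
                "shift": ls_shift.copy(),
                "swap": ls_swap.copy(),
                "pair": ls_pair.copy(),
                "joint": np.array([ls_joint]),
                **{b: ls_block[b].copy() for b in _BLOCKS},
            }

        if not adapting:
            post_burnin_scans += 1
            if (t - config.n_burnin) % config.thin == 0:
                params_out[kept, : len(FIXED_EFFECT_NAMES)] = fixed
                params_out[kept, len(FIXED_EFFECT_NAMES) :] = sigma2
                if linpred_out is not None:
                    linpred_out[kept] = eta
                if latent_out is not None:
                    for b in _BLOCKS:
                        latent_out[b][kept] = blocks[b]
                for b in _BLOCKS:
                    latent_sum[b] += blocks[b]
                    latent_sumsq[b] += blocks[b] ** 2
                kept += 1

    ls_final = {
        "fixed": ls_fixed.copy(),
        "sigma2": ls_sigma2.copy(),
        "shift": ls_shift.copy(),
        "swap": ls_swap.copy(),
        "pair": ls_pair.copy(),
        "joint": np.array([ls_joint]),
        **{b: ls_block[b].copy() for b in _BLOCKS},
    }
    scans = max(post_burnin_scans, 1)
    return {
        "params": params_out,
        "linpred": linpred_out,
        "latents": latent_out,
        "latent_sum": latent_sum,
        "latent_sumsq": latent_sumsq,
        "n_kept": kept,
        "log": {
            "step_sizes_at_burnin_end": {
                k: v.tolist() for k, v in (ls_at_freeze or ls_final).items()
            },
            "step_sizes_final": {k: v.tolist() for k, v in ls_final.items()},
            "acceptance_rates": {
                "fixed": accept_count["fixed"] / (scans * len(FIXED_EFFECT_NAMES)),
                "joint": accept_count["joint"] / scans,
                "sigma2": accept_count["sigma2"] / scans,
                "shift": accept_count["shift"] / scans,
                **{b: accept_count[b] / scans for b in _BLOCKS},
            },
        },
    }


def run_chains(
    dataset: Dataset,
    prior: PriorSpec = PriorSpec(),
    config: MCMCConfig = MCMCConfig(),
) -> PosteriorDraws:
    """Run independent chains from overdispersed starting points.

    Kept draws per chain are ``ceil((n_iterations - n_burnin)/thin)``
    (4000 under the default 100000/20000/20 settings).  Output is fully
    determined by ``config.seed``.
    """
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_single_chain(dataset, prior, config, np.random.default_rng(s))
        for s in child_seeds
    ]
    params = np.stack([c["params"][: c["n_kept"]] for c in chains])
    linpred = (
        np.stack([c["linpred"][: c["n_kept"]] for c in chains])
        if config.store_linpred
        else None
    )
    latent_draws = (
        {
            b: np.stack([c["latents"][b][: c["n_kept"]] for c in chains])
            for b in _BLOCKS
        }
        if config.store_latents
        else None
    )

    total_kept = sum(c["n_kept"] for c in chains)
    rows = []
    for b in _BLOCKS:
        size = chains[0]["latent_sum"][b].shape[0]
        s = sum(c["latent_sum"][b] for c in chains)
        ss = sum(c["latent_sumsq"][b] for c in chains)
        mean = s / max(total_kept, 1)
        var = np.maximum(ss / max(total_kept, 1) - mean**2, 0.0)
        for i in range(size):
            rows.append(
                {
                    "parameter": f"{b}[{i}]",
                    "mean": mean[i],
                    "sd": float(np.sqrt(var[i])),
                }
            )
    latent_summary = pd.DataFrame(rows, columns=["parameter", "mean", "sd"])

    return PosteriorDraws(
        params=params,
        names=list(PARAM_NAMES),
        linpred=linpred,
        latent_summary=latent_summary,
        latent_draws=latent_draws,
        sampler_log={
            "chains": [c["log"] for c in chains],
            "config": {
                "n_iterations": config.n_iterations,
                "n_burnin": config.n_burnin,
                "thin": config.thin,
                "n_chains": config.n_chains,
                "seed": config.seed,
            },
        },
        config=config,
    )


def rhat(chains: np.ndarray) -> float:
    """Split-chain rank-normalized potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Chains are split in half, pooled
    draws are rank-normalized through the standard-normal quantile
    function, and the classic between/within variance ratio is computed.
    Constant draws across all chains give 1.0 by convention.
    """
    from scipy.stats import norm, rankdata

    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if chains.shape[1] < 10:
        raise ValueError("R-hat needs at least 10 draws per chain")
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    if np.all(split == split.flat[0]):
        return 1.0
    ranks = rankdata(split, method="average").reshape(split.shape)
    z = norm.ppf((ranks - 0.375) / (split.size + 0.25))
    m, n = z.shape
    chain_means = z.mean(axis=1)
    W = z.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary per parameter.

    Medians and central 95% intervals are empirical percentiles of the
    pooled draws; sign probabilities are draw fractions (a draw exactly at
    0 counts as positive); the significance flag marks intervals excluding
    0.  R-hat uses the split rank-normalized diagnostic; effective draw
    counts come from ArviZ.
    """
    import arviz as az

    rows = []
    for name in draws.names:
        x = draws.by_chain(name)
        pooled = x.reshape(-1)
        med = float(np.median(pooled))
        lo, hi = (float(v) for v in np.percentile(pooled, [2.5, 97.5]))
        p_pos = float(np.mean(pooled >= 0))
        r = rhat(x) if draws.n_chains >= 2 else np.nan
        ess = float(az.ess(np.ascontiguousarray(x)))
        rows.append(
            {
                "parameter": name,
                "median": med,
                "ci_lo": lo,
                "ci_hi": hi,
                "p_positive": p_pos,
                "p_negative": 1.0 - p_pos,
                "rhat": r,
                "ess": ess,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
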