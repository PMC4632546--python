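"""The two-level binomial-logit model of fertilization success.

Each gravid female's fertilized-unit count is binomial,

    y_i ~ Binomial(n, p_i),    logit(p_i) = eta_i,

with a linear predictor combining quadrat-level effects (local density,
current velocity, water depth, substrate coarseness, the density x flow
interactions, within-bed location, shell length), a date-within-year
random effect gamma, an observation-level overdispersion effect eps, and
a population-replicate intercept

    alpha_{j,t} = alpha_global + a1 P_DEN + a2 CAT + a3 P_DEN*CAT + omega_{j,t}.

Latent effects are normal: gamma ~ N(0, s2_gamma), eps ~ N(0, s2_eps),
omega ~ N(0, s2_omega).  Priors are vague: N(0, variance 100) on every
coefficient ("variance" read literally, sd = 10) and Uniform(0, 100) on
each variance component (applied to the variance itself, not the sd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .design import Dataset, FIXED_EFFECT_NAMES

__all__ = [
    "ModelParameters",
    "PriorSpec",
    "SIGMA2_NAMES",
    "linear_predictor",
    "binomial_loglik_rows",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "predict_fertilization_curve",
]

SIGMA2_NAMES = ["sigma2_gamma", "sigma2_eps", "sigma2_omega"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelParameters:
    """Complete parameter state: fixed effects, variances, latent vectors.

    ``fixed`` follows :data:`allee.design.FIXED_EFFECT_NAMES` order
    (intercept, three population-level coefficients, nine quadrat-level
    coefficients).  ``sigma2`` holds the variances of the date, the
    observation-level (overdispersion) and the population-replicate
    effects, in that order.
    """

    fixed: np.ndarray
    sigma2: np.ndarray
    gamma: np.ndarray
    eps: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.fixed = np.asarray(self.fixed, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.fixed.shape != (len(FIXED_EFFECT_NAMES),):
            raise ValueError(f"fixed must have {len(FIXED_EFFECT_NAMES)} entries")
        if self.sigma2.shape != (3,):
            raise ValueError("sigma2 must have 3 entries (gamma, eps, omega)")

    @classmethod
    def zeros(cls, n_females: int, n_dates: int, n_pops: int) -> "ModelParameters":
        return cls(
            fixed=np.zeros(len(FIXED_EFFECT_NAMES)),
            sigma2=np.ones(3),
            gamma=np.zeros(n_dates),
            eps=np.zeros(n_females),
            omega=np.zeros(n_pops),
        )

    @classmethod
    def from_named(
        cls,
        named: dict[str, float],
        n_females: int = 0,
        n_dates: int = 0,
        n_pops: int = 0,
    ) -> "ModelParameters":
        """Build from a flat named mapping; unnamed entries default to zero."""
        p = cls.zeros(n_females, n_dates, n_pops)
        p.sigma2 = np.array(
            [named.get(k, 0.0) for k in SIGMA2_NAMES], dtype=float
        )
        for i, k in enumerate(FIXED_EFFECT_NAMES):
            p.fixed[i] = named.get(k, 0.0)
        return p

    def to_named(self) -> dict[str, float]:
        out = {k: float(v) for k, v in zip(FIXED_EFFECT_NAMES, self.fixed)}
        out.update({k: float(v) for k, v in zip(SIGMA2_NAMES, self.sigma2)})
        out.update({f"gamma[{i}]": float(v) for i, v in enumerate(self.gamma)})
        out.update({f"eps[{i}]": float(v) for i, v in enumerate(self.eps)})
        out.update({f"omega[{i}]": float(v) for i, v in enumerate(self.omega)})
        return out

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            fixed=self.fixed.copy(),
            sigma2=self.sigma2.copy(),
            gamma=self.gamma.copy(),
            eps=self.eps.copy(),
            omega=self.omega.copy(),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Vague priors: N(0, coef_variance) coefficients, U(0, var_upper) variances."""

    coef_variance: float = 100.0
    var_upper: float = 100.0


def linear_predictor(params: ModelParameters, dataset: Dataset) -> np.ndarray:
    """Logit-scale linear predictor for every female row."""
    if params.gamma.shape[0] != dataset.n_dates:
        raise IndexError("gamma length does not match number of sampling dates")
    if params.omega.shape[0] != dataset.n_pops:
        raise IndexError("omega length does not match number of population replicates")
    if params.eps.shape[0] not in (0, dataset.n_females):
        raise IndexError("eps length does not match number of females")
    eta = dataset.X @ params.fixed
    if params.gamma.shape[0]:
        eta = eta + params.gamma[dataset.date_idx]
    if params.eps.shape[0]:
        eta = eta + params.eps
    if params.omega.shape[0]:
        eta = eta + params.omega[dataset.pop_idx]
    return eta


def binomial_loglik_rows(y: np.ndarray, n: int, eta: np.ndarray) -> np.ndarray:
    """Per-row binomial log-likelihood at logit-scale predictor ``eta``.

    Uses log p = eta - log(1+e^eta) and log(1-p) = -log(1+e^eta) so the
    result stays finite for |eta| up to overflow range (~700 and far
    beyond, since logaddexp is stable).
    """
    log1pexp = np.logaddexp(0.0, eta)
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return const + y * eta - n * log1pexp


def log_likelihood(params: ModelParameters, dataset: Dataset) -> float:
    """Binomial log-likelihood of the full dataset (binomial coefficient included)."""
    if np.any((dataset.y < 0) | (dataset.y > dataset.n)):
        raise ValueError("y outside [0, n]")
    eta = linear_predictor(params, dataset)
    return float(binomial_loglik_rows(dataset.y, dataset.n, eta).sum())


def _normal_logpdf_sum(x: np.ndarray, variance: float) -> float:
    x = np.atleast_1d(x)
    if x.size == 0:
        return 0.0
    if variance <= 0:
        return -np.inf
    return float(
        -0.5 * x.size * (_LOG_2PI + np.log(variance)) - np.sum(x * x) / (2 * variance)
    )


def log_prior(params: ModelParameters, prior: PriorSpec = PriorSpec()) -> float:
    """Joint log-density of coefficients, variance components and latent effects."""
    for s2 in params.sigma2:
        if not (0.0 < s2 < prior.var_upper):
            return -np.inf
    lp = _normal_logpdf_sum(params.fixed, prior.coef_variance)
    lp += -3.0 * np.log(prior.var_upper)  # U(0, var_upper) on each variance
    lp += _normal_logpdf_sum(params.gamma, params.sigma2[0])
    lp += _normal_logpdf_sum(params.eps, params.sigma2[1])
    lp += _normal_logpdf_sum(params.omega, params.sigma2[2])
    return lp


def log_posterior(
    params: ModelParameters, dataset: Dataset, prior: PriorSpec = PriorSpec()
) -> float:
    """Unnormalized log-posterior; -inf outside prior support."""
    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(params, dataset)


def predict_fertilization_curve(
    fixed_draws: np.ndarray,
    spec,
    den_grid: np.ndarray,
    vel: float | None = None,
    dep: float | None = None,
) -> dict[str, np.ndarray]:
    """Posterior fertilization-rate curve over a local-density grid.

    ``fixed_draws`` is (n_draws, 13) in :data:`FIXED_EFFECT_NAMES` order;
    ``den_grid``, ``vel`` and ``dep`` are in natural units and standardized
    through ``spec``.  Covariates not supplied are held at their mean
    (standardized 0), and latent effects at 0, so the curves describe an
    average population on an average date.

    Returns the grid plus pointwise median and central 95% band of p.
    """
    fixed_draws = np.atleast_2d(np.asarray(fixed_draws, dtype=float))
    if fixed_draws.shape[0] == 0:
        raise ValueError("no posterior draws supplied")
    z_den = np.asarray(spec.transform("den", den_grid), dtype=float)
    z_vel = float(spec.transform("vel", vel)) if vel is not None else 0.0
    z_dep = float(spec.transform("dep", dep)) if dep is not None else 0.0

    idx = {k: i for i, k in enumerate(FIXED_EFFECT_NAMES)}
    eta = (
        fixed_draws[:, idx["alpha_global"]][:, None]
        + fixed_draws[:, idx["beta_den"]][:, None] * z_den[None, :]
        + fixed_draws[:, idx["beta_vel"]][:, None] * z_vel
        + fixed_draws[:, idx["beta_dep"]][:, None] * z_dep
        + fixed_draws[:, idx["beta_den_x_vel"]][:, None] * (z_den[None, :] * z_vel)
        + fixed_draws[:, idx["beta_den_x_dep"]][:, None] * (z_den[None, :] * z_dep)
    )
    p = expit(eta)
    return {
        "den": np.asarray(den_grid, dtype=float),
        "median": np.median(p, axis=0),
        "lo": np.percentile(p, 2.5, axis=0),
        "hi": np.percentile(p, 97.5, axis=0),
    }
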