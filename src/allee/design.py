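"""Design-matrix construction: covariate standardization and collinearity screen.

All eight explanatory variables (six quadrat-level, two population-level,
the latter joined onto female rows by population replicate) are z-scored
before modelling; interaction columns are products of the standardized
main-effect columns so that main effects keep their at-the-mean
interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import FemaleRecord, PopulationRecord, MissingPopulationError

__all__ = [
    "COVARIATES",
    "FIXED_EFFECT_NAMES",
    "StandardizationSpec",
    "Dataset",
    "DegenerateCovariateError",
    "standardize",
    "build_design",
    "correlation_screen",
]

#: The eight main explanatory variables, in design order.
COVARIATES = ["p_den", "cat", "den", "vel", "dep", "sub", "loc", "shell"]

#: Fixed-effect names matching the design-matrix columns (intercept first).
FIXED_EFFECT_NAMES = [
    "alpha_global",
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
]


class DegenerateCovariateError(ValueError):
    """A covariate has zero sample variance and cannot be standardized."""


@dataclass(frozen=True)
class StandardizationSpec:
    """Per-covariate mean and sample standard deviation (n-1 denominator).

    Stored so that prediction axes can be mapped between natural units and
    the standardized scale used for fitting.
    """

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise DegenerateCovariateError(f"{name}: sd={sd} not positive")

    def transform(self, name: str, value):
        return (np.asarray(value, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, zvalue):
        return np.asarray(zvalue, dtype=float) * self.sds[name] + self.means[name]

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationSpec":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]))


@dataclass
class Dataset:
    """Standardized, index-coded data ready for the hierarchical model.

    ``X`` has 13 columns in ``FIXED_EFFECT_NAMES`` order: an intercept,
    the three population-level terms, and the nine quadrat-level terms.
    ``date_idx`` codes sampling date nested within year; ``pop_idx`` codes
    the population x year replicate.
    """

    y: np.ndarray
    n: int
    X: np.ndarray
    date_idx: np.ndarray
    pop_idx: np.ndarray
    date_labels: list
    pop_labels: list
    spec: StandardizationSpec
    natural: pd.DataFrame  # covariates in natural units, one row per female
    #: include the observation-level overdispersion effect; disabled only
    #: for reduced submodels (e.g. the single-proportion conjugate check)
    overdispersion: bool = True

    @property
    def n_females(self) -> int:
        return self.y.shape[0]

    @property
    def n_dates(self) -> int:
        return len(self.date_labels)

    @property
    def n_pops(self) -> int:
        return len(self.pop_labels)


def _covariate_frame(
    females: list[FemaleRecord], populations: list[PopulationRecord]
) -> pd.DataFrame:
    pop_map = {(p.population_id, p.year): p for p in populations}
    rows = []
    for r in females:
        key = (r.population_id, r.year)
        if key not in pop_map:
            raise MissingPopulationError(f"no population record for {key}")
        p = pop_map[key]
        rows.append(
            {
                "female_id": r.female_id,
                "population_id": r.population_id,
                "date": r.date,
                "year": r.year,
                "y": r.y,
                "n": r.n,
                "den": r.den,
                "vel": r.vel,
                "dep": r.dep,
                "sub": r.sub,
                "loc": r.loc,
                "shell": r.shell,
                "p_den": p.p_den,
                "cat": p.cat,
            }
        )
    return pd.DataFrame(rows)


def standardize(
    females: list[FemaleRecord], populations: list[PopulationRecord]
) -> tuple[pd.DataFrame, StandardizationSpec]:
    """Z-score the eight main covariates over female rows.

    Returns the standardized main-effect columns (plus the four interaction
    columns, computed as products of standardized mains) and the
    standardization spec for back-transformation.
    """
    frame = _covariate_frame(females, populations)
    means, sds = {}, {}
    z = pd.DataFrame(index=frame.index)
    for name in COVARIATES:
        col = frame[name].to_numpy(dtype=float)
        mu, sd = float(col.mean()), float(col.std(ddof=1))
        if not sd > 0:
            raise DegenerateCovariateError(f"covariate {name!r} is constant")
        means[name], sds[name] = mu, sd
        z[name] = (col - mu) / sd
    z["den_x_vel"] = z["den"] * z["vel"]
    z["den_x_dep"] = z["den"] * z["dep"]
    z["den_x_sub"] = z["den"] * z["sub"]
    z["pden_x_cat"] = z["p_den"] * z["cat"]
    return z, StandardizationSpec(means=means, sds=sds)


def build_design(
    females: list[FemaleRecord], populations: list[PopulationRecord]
) -> Dataset:
    """Assemble the full model dataset from usable female and population records."""
    if any(not r.usable for r in females):
        raise ValueError("build_design expects usable records; apply filter_usable first")
    frame = _covariate_frame(females, populations)
    z, spec = standardize(females, populations)

    X = np.column_stack(
        [
            np.ones(len(frame)),
            z["p_den"],
            z["cat"],
            z["pden_x_cat"],
            z["den"],
            z["vel"],
            z["dep"],
            z["sub"],
            z["den_x_vel"],
            z["den_x_dep"],
            z["den_x_sub"],
            z["loc"],
            z["shell"],
        ]
    )

    # date nested within year by construction of the label
    date_keys = list(zip(frame["year"], frame["date"]))
    date_labels = sorted(set(date_keys))
    date_idx = np.array([date_labels.index(k) for k in date_keys], dtype=np.intp)
    pop_keys = list(zip(frame["population_id"], frame["year"]))
    pop_labels = sorted(set(pop_keys))
    pop_idx = np.array([pop_labels.index(k) for k in pop_keys], dtype=np.intp)

    n_values = frame["n"].unique()
    if len(n_values) != 1:
        raise ValueError(f"total units counted must be constant, got {n_values}")

    return Dataset(
        y=frame["y"].to_numpy(dtype=np.int64),
        n=int(n_values[0]),
        X=X,
        date_idx=date_idx,
        pop_idx=pop_idx,
        date_labels=date_labels,
        pop_labels=pop_labels,
        spec=spec,
        natural=frame,
    )


def correlation_screen(
    z: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, bool]:
    """Pairwise Pearson correlations among the eight main covariates.

    The model's explanatory variables are screened for collinearity; the
    screen passes iff every off-diagonal |r| is below ``threshold``.
    """
    cols = [c for c in COVARIATES if c in z.columns]
    if len(z) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    corr = z[cols].corr(method="pearson")
    off_diag = corr.to_numpy()[~np.eye(len(cols), dtype=bool)]
    passed = bool(np.all(np.abs(off_diag) < threshold))
    return corr, passed
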