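"""Domain records for the mussel fertilization study.

One row of the analysis is a gravid female whose brooded eggs were
subsampled and scored as fertilized eggs, developing glochidia, or
unfertilized eggs, in replicate counts of 100 units each.  Populations
are discrete mussel beds sampled in one or more years; a population
sampled in two years contributes two population replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EggCount",
    "SubstrateComposition",
    "FemaleRecord",
    "PopulationRecord",
    "MalformedCountError",
    "CovariateValidationError",
    "MissingPopulationError",
    "tally_fertilization",
    "substrate_coarseness",
    "filter_usable",
    "derive_population_density",
]

UNITS_PER_REPLICATE = 100

SUBSTRATE_CODES = {"sand": 1.0, "gravel": 2.0, "cobble": 3.0, "boulder": 4.0}


class MalformedCountError(ValueError):
    """Egg counts inconsistent with the 100-units-per-replicate protocol."""


class CovariateValidationError(ValueError):
    """A covariate violates its documented domain."""


class MissingPopulationError(KeyError):
    """No records exist for the requested population replicate."""


@dataclass(frozen=True)
class EggCount:
    """Total egg-category counts for one female, summed over replicates.

    Each counting replicate stops when fertilized eggs, glochidia and
    unfertilized eggs together reach exactly 100 units; ``n_replicates``
    replicates are performed (3 in the field protocol, giving 300 units).
    """

    n_fertilized: int
    n_glochidia: int
    n_unfertilized: int
    n_replicates: int = 3

    def __post_init__(self) -> None:
        counts = (self.n_fertilized, self.n_glochidia, self.n_unfertilized)
        if any(c < 0 for c in counts) or self.n_replicates < 1:
            raise MalformedCountError(f"negative count in {self!r}")
        if sum(counts) != UNITS_PER_REPLICATE * self.n_replicates:
            raise MalformedCountError(
                f"categories sum to {sum(counts)}, expected "
                f"{UNITS_PER_REPLICATE * self.n_replicates} "
                f"({self.n_replicates} replicates of {UNITS_PER_REPLICATE})"
            )


@dataclass(frozen=True)
class SubstrateComposition:
    """Visual cover proportions of the four substrate categories in a quadrat."""

    sand: float
    gravel: float
    cobble: float
    boulder: float

    def __post_init__(self) -> None:
        props = (self.sand, self.gravel, self.cobble, self.boulder)
        if any(p < 0 or p > 1 for p in props):
            raise CovariateValidationError(f"proportions outside [0,1]: {props}")
        if abs(sum(props) - 1.0) > 1e-9:
            raise CovariateValidationError(
                f"proportions sum to {sum(props)!r}, expected 1"
            )


@dataclass(frozen=True)
class FemaleRecord:
    """One gravid female: fertilization outcome plus quadrat-level covariates.

    ``usable`` is False when fertilized and unfertilized eggs could not be
    discriminated for this female; such records are dropped before analysis.
    """

    female_id: str
    population_id: str
    date: str
    year: int
    y: int
    n: int
    den: float  # local conspecific adult density, individuals per 0.25 m^2
    vel: float  # current velocity, cm s^-1
    dep: float  # water depth, cm
    sub: float  # substrate coarseness index, 1-4
    loc: float  # distance (m) from the upstream edge of the population
    shell: float  # shell length, mm
    usable: bool = True

    def __post_init__(self) -> None:
        if not self.usable:
            return
        if not (0 <= self.y <= self.n):
            raise CovariateValidationError(f"y={self.y} outside [0, {self.n}]")
        if self.den < 0 or self.den != int(self.den):
            raise CovariateValidationError(f"den={self.den} not a count")
        if self.vel <= 0 or self.dep <= 0 or self.shell <= 0:
            raise CovariateValidationError(
                f"vel/dep/shell must be positive: {self.vel}, {self.dep}, {self.shell}"
            )
        if not (1.0 <= self.sub <= 4.0):
            raise CovariateValidationError(f"sub={self.sub} outside [1, 4]")
        if self.loc < 0:
            raise CovariateValidationError(f"loc={self.loc} negative")


@dataclass(frozen=True)
class PopulationRecord:
    """One population x year replicate with its population-scale covariates."""

    population_id: str
    year: int
    p_den: float  # mean population density, individuals per 0.25 m^2
    cat: float  # catchment area, km^2

    def __post_init__(self) -> None:
        if self.p_den < 0:
            raise CovariateValidationError(f"p_den={self.p_den} negative")
        if self.cat <= 0:
            raise CovariateValidationError(f"cat={self.cat} not positive")


def tally_fertilization(egg_count: EggCount) -> tuple[int, int]:
    """Tally a female's fertilization outcome.

    Returns ``(y, n)`` where ``y`` counts fertilized eggs plus developing
    glochidia (both indicate successful fertilization) and ``n`` is the
    total units counted, 100 per replicate.
    """
    y = egg_count.n_fertilized + egg_count.n_glochidia
    n = UNITS_PER_REPLICATE * egg_count.n_replicates
    return y, n


def substrate_coarseness(comp: SubstrateComposition) -> float:
    """Cover-weighted substrate code: sum of code x proportion, in [1, 4]."""
    return (
        SUBSTRATE_CODES["sand"] * comp.sand
        + SUBSTRATE_CODES["gravel"] * comp.gravel
        + SUBSTRATE_CODES["cobble"] * comp.cobble
        + SUBSTRATE_CODES["boulder"] * comp.boulder
    )


def filter_usable(records: list[FemaleRecord]) -> list[FemaleRecord]:
    """Drop females whose egg samples could not be scored, preserving order."""
    return [r for r in records if r.usable]


def derive_population_density(
    records: list[FemaleRecord], population_id: str, year: int
) -> float:
    """Mean local conspecific density over a population replicate's usable records."""
    dens = [
        r.den
        for r in records
        if r.usable and r.population_id == population_id and r.year == year
    ]
    if not dens:
        raise MissingPopulationError(
            f"no usable records for population {population_id!r}, year {year}"
        )
    return float(sum(dens) / len(dens))
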