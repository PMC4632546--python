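"""Delimited-text readers and writers for study tables.

Females: ``female_id, population_id, date, year, y, n, den, vel, dep, sub,
loc, shell, usable``.  Populations: ``population_id, year, p_den, cat``.
The standardization spec travels as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .design import StandardizationSpec
from .records import FemaleRecord, PopulationRecord

__all__ = [
    "read_females",
    "write_females",
    "read_populations",
    "write_populations",
    "read_standardization",
    "write_standardization",
]

FEMALE_COLUMNS = [
    "female_id",
    "population_id",
    "date",
    "year",
    "y",
    "n",
    "den",
    "vel",
    "dep",
    "sub",
    "loc",
    "shell",
    "usable",
]

POPULATION_COLUMNS = ["population_id", "year", "p_den", "cat"]


def read_females(path: str | Path) -> list[FemaleRecord]:
    df = pd.read_csv(path, dtype={"female_id": str, "population_id": str, "date": str})
    missing = set(FEMALE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"females table missing columns: {sorted(missing)}")
    if df[FEMALE_COLUMNS].isna().any().any():
        raise ValueError("missing covariate cells are not allowed (no imputation)")
    return [
        FemaleRecord(
            female_id=row.female_id,
            population_id=row.population_id,
            date=row.date,
            year=int(row.year),
            y=int(row.y),
            n=int(row.n),
            den=float(row.den),
            vel=float(row.vel),
            dep=float(row.dep),
            sub=float(row.sub),
            loc=float(row.loc),
            shell=float(row.shell),
            usable=bool(row.usable),
        )
        for row in df.itertuples(index=False)
    ]


def write_females(records: list[FemaleRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=FEMALE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_populations(path: str | Path) -> list[PopulationRecord]:
    df = pd.read_csv(path, dtype={"population_id": str})
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"populations table missing columns: {sorted(missing)}")
    if df[POPULATION_COLUMNS].isna().any().any():
        raise ValueError("missing cells are not allowed in the population table")
    return [
        PopulationRecord(
            population_id=row.population_id,
            year=int(row.year),
            p_den=float(row.p_den),
            cat=float(row.cat),
        )
        for row in df.itertuples(index=False)
    ]


def write_populations(records: list[PopulationRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=POPULATION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def write_standardization(spec: StandardizationSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2, sort_keys=True))


def read_standardization(path: str | Path) -> StandardizationSpec:
    return StandardizationSpec.from_dict(json.loads(Path(path).read_text()))
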