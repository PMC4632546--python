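import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from allee.records import FemaleRecord, PopulationRecord


def make_female(i, pop="neppu-1", year=2012, date="2012-06-27", y=150, **kw):
    defaults = dict(
        female_id=f"F{i:03d}",
        population_id=pop,
        date=date,
        year=year,
        y=y,
        n=300,
        den=10 + (i % 5),
        vel=8.0 + i,
        dep=25.0 + (i % 7),
        sub=2.5 + 0.1 * (i % 4),
        loc=float(i),
        shell=70.0 + i,
        usable=True,
    )
    defaults.update(kw)
    return FemaleRecord(**defaults)


@pytest.fixture
def small_study():
    """Two beds x two dates, 8 females, with matching population records."""
    females = [
        make_female(i, pop="neppu-1", date="2012-06-27", y=100 + 10 * i)
        for i in range(4)
    ] + [
        make_female(
            4 + i, pop="raiba-1", date="2012-07-03", y=200 + 5 * i, den=20 + i
        )
        for i in range(4)
    ]
    pops = [
        PopulationRecord("neppu-1", 2012, p_den=11.5, cat=45.0),
        PopulationRecord("raiba-1", 2012, p_den=21.5, cat=120.0),
    ]
    return females, pops


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
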