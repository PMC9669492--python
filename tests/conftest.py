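import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rgsc import (
    Construct,
    GridElement,
    RatingScale,
    RepertoryGrid,
    fixture_cohort_dir,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

THREE_ELEMENTS = [
    GridElement("present_self", "present self"),
    GridElement("self_before_lesion", "self before the lesion"),
    GridElement("ideal_self", "ideal self"),
]


def make_grid(ratings, pid="t1", elements=None, scale=None):
    """Build a grid around a ratings matrix, inventing pole labels."""
    ratings = np.atleast_2d(np.asarray(ratings, dtype=int))
    c = ratings.shape[0]
    return RepertoryGrid(
        participant_id=pid,
        constructs=[Construct(f"left{i}", f"right{i}") for i in range(c)],
        elements=elements or list(THREE_ELEMENTS),
        ratings=ratings,
        scale=scale or RatingScale(),
    )


def random_grid(rng, c=None, e=3, pid="r"):
    c = c if c is not None else int(rng.integers(1, 26))
    elements = list(THREE_ELEMENTS)
    for k in range(e - 3):
        elements.append(GridElement("other", f"other {k}"))
    return make_grid(rng.integers(1, 8, size=(c, e)), pid=pid, elements=elements[:e])


@pytest.fixture(scope="session")
def fixture_dir():
    return str(fixture_cohort_dir())


@pytest.fixture(scope="session")
def fixture_measures(fixture_dir):
    from rgsc import read_measures_table

    return read_measures_table(f"{fixture_dir}/measures.csv")


@pytest.fixture(scope="session")
def fixture_grids(fixture_dir):
    from rgsc import read_cohort

    return read_cohort(fixture_dir)
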