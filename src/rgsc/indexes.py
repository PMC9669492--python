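"""Grid-derived self-concept indexes.

Three index families are computed from a repertory grid:

* **Standardized Euclidean distance** between two elements ``x`` and ``y``::

      ED(x, y) = sqrt( sum_i (x_i - y_i)^2 ) / ( MD * sqrt(C) )

  where ``x_i``, ``y_i`` are the ratings of the two elements on construct
  ``i``, ``MD`` is the maximum possible rating difference (6 on the 1-7
  scale) and ``C`` is the number of constructs.  The normalization puts the
  distance in [0, 1], with 1 the maximum possible discrepancy.

* **Opposed-pole proportion**: the fraction of constructs on which the two
  elements are rated at opposite pole bands (one in 1-3, the other in 5-7).
  A midpoint rating (4) on either element never counts as opposed.

* **Polarization**: the fraction of ratings at the exact scale extremes
  (1 or 7), per element column or over the whole matrix — an index of
  extreme, rigid construing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import NAMED_ROLES, RepertoryGrid

__all__ = [
    "ElementPair",
    "GridIndexSet",
    "euclidean_distance",
    "all_pairwise_distances",
    "opposed_pole_proportion",
    "element_polarization",
    "total_polarization",
    "compute_indexes",
    "indexes_table",
    "INDEX_COLUMNS",
]

# canonical ordering of element keys inside a pair
_ROLE_ORDER = {r: i for i, r in enumerate(NAMED_ROLES)}


def _order_key(key: str):
    return (_ROLE_ORDER.get(key, len(_ROLE_ORDER)), key)


@dataclass(frozen=True)
class ElementPair:
    """Unordered pair of element keys: ``ElementPair(a, b) == ElementPair(b, a)``."""

    first: str
    second: str

    def __post_init__(self):
        if self.first == self.second:
            raise ValueError(f"element pair needs two distinct elements, got {self.first!r} twice")
        a, b = sorted((self.first, self.second), key=_order_key)
        object.__setattr__(self, "first", a)
        object.__setattr__(self, "second", b)


@dataclass
class GridIndexSet:
    """All derived indexes for one participant's grid."""

    participant_id: str
    distances: dict[ElementPair, float]
    opposed_proportions: dict[ElementPair, float]
    element_polarization: dict[str, float]
    total_polarization: float
    n_constructs: int


def _columns(grid: RepertoryGrid, a: str, b: str):
    return grid.column(a).astype(float), grid.column(b).astype(float)


def euclidean_distance(grid: RepertoryGrid, role_a: str, role_b: str) -> float:
    """Standardized Euclidean distance between two elements, in [0, 1].

    Symmetric in the pair; 0 iff the two rating columns are identical and 1
    iff every construct shows the maximum possible rating difference.
    """
    x, y = _columns(grid, role_a, role_b)
    md = grid.scale.max_difference
    c = grid.n_constructs
    # dividing inside the root keeps the maximal case exactly 1.0
    return float(math.sqrt(np.sum((x - y) ** 2) / (md * md * c)))


def all_pairwise_distances(grid: RepertoryGrid) -> dict[ElementPair, float]:
    """ED for every unordered pair of elements (3 pairs for the standard
    three-element self grid)."""
    keys = [e.key() for e in grid.elements]
    out: dict[ElementPair, float] = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            out[ElementPair(keys[i], keys[j])] = euclidean_distance(
                grid, keys[i], keys[j]
            )
    return out


def opposed_pole_proportion(grid: RepertoryGrid, role_a: str, role_b: str) -> float:
    """Fraction of constructs rated at opposite pole bands on the two
    elements (one rating in the left band, the other in the right band)."""
    x, y = grid.column(role_a), grid.column(role_b)
    s = grid.scale
    left_x = x < s.midpoint
    right_x = x > s.midpoint
    left_y = y < s.midpoint
    right_y = y > s.midpoint
    opposed = (left_x & right_y) | (right_x & left_y)
    return float(np.count_nonzero(opposed)) / grid.n_constructs


def element_polarization(grid: RepertoryGrid, role: str) -> float:
    """Fraction of a column's ratings at the exact scale extremes."""
    col = grid.column(role)
    s = grid.scale
    n_extreme = np.count_nonzero((col == s.min_rating) | (col == s.max_rating))
    return float(n_extreme) / grid.n_constructs


def total_polarization(grid: RepertoryGrid) -> float:
    """Fraction of all C x E matrix cells at the exact scale extremes.

    Equals the equal-weight mean of the per-element polarizations, since
    every column has C cells.
    """
    s = grid.scale
    n_extreme = np.count_nonzero(
        (grid.ratings == s.min_rating) | (grid.ratings == s.max_rating)
    )
    return float(n_extreme) / grid.ratings.size


def compute_indexes(grid: RepertoryGrid) -> GridIndexSet:
    """All index families for one grid, at full floating precision."""
    keys = [e.key() for e in grid.elements]
    opposed = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            opposed[ElementPair(keys[i], keys[j])] = opposed_pole_proportion(
                grid, keys[i], keys[j]
            )
    return GridIndexSet(
        participant_id=grid.participant_id,
        distances=all_pairwise_distances(grid),
        opposed_proportions=opposed,
        element_polarization={k: element_polarization(grid, k) for k in keys},
        total_polarization=total_polarization(grid),
        n_constructs=grid.n_constructs,
    )


# tidy serialization for the standard three-element self grid
_PAIRS = (
    ("present_before", ElementPair("present_self", "self_before_lesion")),
    ("present_ideal", ElementPair("present_self", "ideal_self")),
    ("before_ideal", ElementPair("self_before_lesion", "ideal_self")),
)
_ELEMS = (
    ("present", "present_self"),
    ("before", "self_before_lesion"),
    ("ideal", "ideal_self"),
)
INDEX_COLUMNS = (
    ["participant_id"]
    + [f"ed_{n}" for n, _ in _PAIRS]
    + [f"opp_{n}" for n, _ in _PAIRS]
    + [f"pol_{n}" for n, _ in _ELEMS]
    + ["pol_total", "n_constructs"]
)


def indexes_table(index_sets) -> "pandas.DataFrame":
    """One tidy row per participant for the three-element self grid."""
    import pandas as pd

    rows = []
    for s in index_sets:
        row: dict = {"participant_id": s.participant_id}
        for name, pair in _PAIRS:
            row[f"ed_{name}"] = s.distances[pair]
            row[f"opp_{name}"] = s.opposed_proportions[pair]
        for name, role in _ELEMS:
            row[f"pol_{name}"] = s.element_polarization[role]
        row["pol_total"] = s.total_polarization
        row["n_constructs"] = s.n_constructs
        rows.append(row)
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)
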