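"""Data types, validation and file I/O for repertory grids.

A repertory grid is the product of a semi-structured interview in which a
participant rates a set of *elements* (here: the present self, the self
before the lesion, and the ideal self) on personally elicited bipolar
*constructs* (e.g. ``happy -- sad``) using a 7-point Likert scale.  Ratings
1--3 lean toward the left pole, 4 is the midpoint, and 5--7 lean toward the
right pole.  The grid is stored constructs-as-rows, elements-as-columns.

This module also carries the Galveston Orientation and Amnesia Test (GOAT)
inclusion rule used to establish emergence from post-traumatic amnesia.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PRESENT_SELF",
    "SELF_BEFORE_LESION",
    "IDEAL_SELF",
    "OTHER",
    "NAMED_ROLES",
    "RatingScale",
    "Construct",
    "GridElement",
    "RepertoryGrid",
    "GoatRecord",
    "GridParseError",
    "validate_grid",
    "read_grid_table",
    "write_grid_table",
    "read_cohort",
    "write_cohort",
    "read_measures_table",
    "goat_eligible",
]

# Element roles.  The three named roles are the ones the self-concept
# analyses use; ``other`` admits arbitrary extra elements (e.g. "my mother")
# so the library generalizes to standard grids.
PRESENT_SELF = "present_self"
SELF_BEFORE_LESION = "self_before_lesion"
IDEAL_SELF = "ideal_self"
OTHER = "other"
NAMED_ROLES = (PRESENT_SELF, SELF_BEFORE_LESION, IDEAL_SELF)

CONSTRUCT_SOURCES = ("self_generated", "list_supplied")


@dataclass(frozen=True)
class RatingScale:
    """Bounds and midpoint of the Likert rating scale.

    The default is the 7-point scale: left-pole band {1, 2, 3}, midpoint 4,
    right-pole band {5, 6, 7}.  ``max_difference`` (the largest possible
    rating gap, denoted MD in the distance formula) derives from the bounds.
    """

    min_rating: int = 1
    max_rating: int = 7
    midpoint: int = 4

    def __post_init__(self) -> None:
        if not (self.min_rating < self.midpoint < self.max_rating):
            raise ValueError(
                f"rating scale requires min < midpoint < max, got "
                f"{self.min_rating} / {self.midpoint} / {self.max_rating}"
            )

    @property
    def max_difference(self) -> int:
        return self.max_rating - self.min_rating

    def in_left_band(self, r) -> bool:
        return self.min_rating <= r < self.midpoint

    def in_right_band(self, r) -> bool:
        return self.midpoint < r <= self.max_rating

    def is_extreme(self, r) -> bool:
        return r == self.min_rating or r == self.max_rating


@dataclass(frozen=True)
class Construct:
    """A bipolar discrimination forming one grid row (e.g. happy -- sad)."""

    left_pole: str
    right_pole: str
    source: str = "self_generated"


@dataclass(frozen=True)
class GridElement:
    """An entity rated on every construct, forming one grid column."""

    role: str
    label: str = ""

    def key(self) -> str:
        """Identity used to key element pairs: the role for the three named
        roles, ``other:<label>`` otherwise."""
        if self.role in NAMED_ROLES:
            return self.role
        return f"{OTHER}:{self.label}"


@dataclass
class RepertoryGrid:
    """One participant's constructs x elements integer rating matrix."""

    participant_id: str
    constructs: list[Construct]
    elements: list[GridElement]
    ratings: np.ndarray  # shape (C, E), integer
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=int)

    @property
    def n_constructs(self) -> int:
        return len(self.constructs)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_index(self, role_or_key: str) -> int:
        """Index of the element whose role (or ``other:<label>`` key)
        matches; raises ``KeyError`` naming the role if absent."""
        for i, e in enumerate(self.elements):
            if e.role == role_or_key or e.key() == role_or_key:
                return i
        raise KeyError(
            f"grid {self.participant_id!r} has no element with role "
            f"{role_or_key!r}"
        )

    def column(self, role_or_key: str) -> np.ndarray:
        """Rating column for one element, length C."""
        return self.ratings[:, self.element_index(role_or_key)]


@dataclass
class GoatRecord:
    """Daily GOAT scores (0-100) for one participant during hospitalization."""

    participant_id: str
    daily_scores: list[int]


class GridParseError(ValueError):
    """Raised when a grid table file is malformed; names line/column."""


def validate_grid(grid: RepertoryGrid) -> list[str]:
    """Check every grid invariant; return human-readable violations.

    Returns an empty list iff the grid is valid.  Row/column positions in
    messages are 1-based.  Missing (non-integer) cells are impossible by
    construction since ``ratings`` is an integer array; grids with NaN-like
    input fail at array conversion upstream, consistent with the fail-fast
    policy on incomplete data.
    """
    v: list[str] = []
    s = grid.scale
    if grid.n_constructs < 1:
        v.append("grid must have at least 1 construct")
    if grid.n_elements < 2:
        v.append("grid must have at least 2 elements")
    if grid.ratings.ndim != 2 or grid.ratings.shape != (
        grid.n_constructs,
        grid.n_elements,
    ):
        v.append(
            f"ratings matrix shape {grid.ratings.shape} does not match "
            f"{grid.n_constructs} constructs x {grid.n_elements} elements"
        )
        return v  # cell checks below would be meaningless
    for i, c in enumerate(grid.constructs):
        if not c.left_pole or not c.right_pole:
            v.append(f"construct {i + 1}: empty pole label")
        elif c.left_pole == c.right_pole:
            v.append(f"construct {i + 1}: identical pole labels {c.left_pole!r}")
        if c.source not in CONSTRUCT_SOURCES:
            v.append(f"construct {i + 1}: unknown source {c.source!r}")
    seen_roles: dict[str, int] = {}
    for j, e in enumerate(grid.elements):
        if e.role not in NAMED_ROLES and e.role != OTHER:
            v.append(f"element {j + 1}: unknown role {e.role!r}")
        if e.role in NAMED_ROLES:
            if e.role in seen_roles:
                v.append(
                    f"element {j + 1}: role {e.role!r} already used by "
                    f"element {seen_roles[e.role] + 1}"
                )
            else:
                seen_roles[e.role] = j
    rows, cols = np.nonzero(
        (grid.ratings < s.min_rating) | (grid.ratings > s.max_rating)
    )
    for i, j in zip(rows, cols):
        v.append(
            f"rating {grid.ratings[i, j]} at construct {i + 1}, element "
            f"{j + 1} outside scale [{s.min_rating}, {s.max_rating}]"
        )
    return v


# ---------------------------------------------------------------------------
# Grid table file format (UTF-8 CSV):
#   row 1:   left_pole,<element label 1>,...,<element label E>,right_pole
#   row 2:   #roles,<role 1>,...,<role E>,
#   rows 3+: <left pole label>,<E integer ratings>,<right pole label>
# Participant id and scale bounds live in a cohort-level sidecar (JSON/YAML)
# keyed by participant_id; by default the id is the file stem.
# ---------------------------------------------------------------------------

_VALID_ROLES = set(NAMED_ROLES) | {OTHER}


def read_grid_table(
    path,
    *,
    participant_id: str | None = None,
    scale: RatingScale | None = None,
    sources: Sequence[str] | None = None,
) -> RepertoryGrid:
    """Parse one grid table CSV into a :class:`RepertoryGrid`.

    Raises :class:`GridParseError` naming the offending line/column on a
    malformed header, a non-integer rating, or a dimension mismatch.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise GridParseError(f"{path.name}: expected header, roles row and "
                             f"at least one construct row, got {len(rows)} rows")
    header = rows[0]
    if len(header) < 4 or header[0] != "left_pole" or header[-1] != "right_pole":
        raise GridParseError(
            f"{path.name} line 1: header must be "
            f"'left_pole,<labels...>,right_pole', got {','.join(header)!r}"
        )
    labels = header[1:-1]
    n_elem = len(labels)
    roles_row = rows[1]
    if not roles_row or roles_row[0] != "#roles":
        raise GridParseError(f"{path.name} line 2: expected '#roles' row")
    roles = [r for r in roles_row[1:] if r != ""]
    if len(roles) != n_elem:
        raise GridParseError(
            f"{path.name} line 2: {len(roles)} roles for {n_elem} elements"
        )
    for j, r in enumerate(roles):
        if r not in _VALID_ROLES:
            raise GridParseError(
                f"{path.name} line 2, column {j + 2}: unknown role {r!r}"
            )
    elements = [GridElement(role=r, label=lbl) for r, lbl in zip(roles, labels)]

    constructs: list[Construct] = []
    ratings: list[list[int]] = []
    for lineno, row in enumerate(rows[2:], start=3):
        if not row or (len(row) == 1 and row[0] == ""):
            continue  # ignore trailing blank line
        if len(row) != n_elem + 2:
            raise GridParseError(
                f"{path.name} line {lineno}: expected {n_elem + 2} fields "
                f"(left pole, {n_elem} ratings, right pole), got {len(row)}"
            )
        cells = []
        for j, cell in enumerate(row[1:-1]):
            try:
                cells.append(int(cell))
            except ValueError:
                raise GridParseError(
                    f"{path.name} line {lineno}, column {j + 2}: "
                    f"non-integer rating {cell!r}"
                ) from None
        src = "self_generated"
        if sources is not None and len(constructs) < len(sources):
            src = sources[len(constructs)]
        constructs.append(Construct(row[0], row[-1], source=src))
        ratings.append(cells)

    return RepertoryGrid(
        participant_id=participant_id or path.stem,
        constructs=constructs,
        elements=elements,
        ratings=np.array(ratings, dtype=int),
        scale=scale or RatingScale(),
    )


def write_grid_table(grid: RepertoryGrid, path) -> None:
    """Write a grid in the grid table CSV format (round-trips with
    :func:`read_grid_table`)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["left_pole", *[e.label for e in grid.elements], "right_pole"])
        w.writerow(["#roles", *[e.role for e in grid.elements], ""])
        for c, row in zip(grid.constructs, grid.ratings):
            w.writerow([c.left_pole, *[int(r) for r in row], c.right_pole])


def write_cohort(grids: Iterable[RepertoryGrid], directory) -> None:
    """Write one grid CSV per participant plus a ``meta.json`` sidecar
    holding participant ids, scale bounds and construct sources."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict[str, dict] = {}
    for g in grids:
        write_grid_table(g, directory / f"{g.participant_id}.csv")
        meta[g.participant_id] = {
            "scale": {
                "min_rating": g.scale.min_rating,
                "max_rating": g.scale.max_rating,
                "midpoint": g.scale.midpoint,
            },
            "sources": [c.source for c in g.constructs],
        }
    with open(directory / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cohort(directory) -> list[RepertoryGrid]:
    """Read every ``*.csv`` grid in a directory (sorted by participant id),
    applying the ``meta.json`` sidecar when present."""
    directory = Path(directory)
    meta: Mapping[str, dict] = {}
    meta_path = directory / "meta.json"
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            meta = json.load(fh)
    grids = []
    for p in sorted(directory.glob("*.csv")):
        if p.name == "measures.csv":  # reserved for the instrument table
            continue
        pid = p.stem
        m = meta.get(pid, {})
        scale = None
        if "scale" in m:
            scale = RatingScale(**m["scale"])
        grids.append(
            read_grid_table(
                p, participant_id=pid, scale=scale, sources=m.get("sources")
            )
        )
    return grids


def read_measures_table(path):
    """Read the per-participant instrument item table.

    One row per participant; columns ``participant_id``, ``phq9_1..9``,
    ``gad7_1..7``, ``swls_1..5``, ``qolibri_1..37`` and optional
    ``goat_day1..K`` columns.  Returned as a pandas DataFrame with
    ``participant_id`` as a plain column.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ValueError(f"{Path(path).name}: missing participant_id column")
    return df


def goat_eligible(
    record: GoatRecord, threshold: int = 75, consecutive_days: int = 2
) -> bool:
    """Post-traumatic-amnesia emergence rule: true iff some run of
    ``consecutive_days`` successive daily scores are all >= ``threshold``
    (inclusive: a score of exactly 75 counts).
    """
    scores = list(record.daily_scores)
    if not scores:
        raise ValueError(f"participant {record.participant_id!r}: no GOAT scores")
    run = 0
    for s in scores:
        run = run + 1 if s >= threshold else 0
        if run >= consecutive_days:
            return True
    return False
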