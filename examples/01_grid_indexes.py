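"""Compute the three grid index families for a single hand-built grid.

A participant rated five bipolar constructs for the present self, the self
before the lesion, and the ideal self on the 1-7 scale.  We compute the
standardized Euclidean distances between the elements, the proportion of
constructs rated at opposed poles, and the polarization proportions.
"""

import numpy as np

from rgsc import (
    Construct,
    GridElement,
    RepertoryGrid,
    all_pairwise_distances,
    element_polarization,
    opposed_pole_proportion,
    total_polarization,
    validate_grid,
)

grid = RepertoryGrid(
    participant_id="demo",
    constructs=[
        Construct("happy", "sad"),
        Construct("calm", "nervous"),
        Construct("active", "passive"),
        Construct("confident", "insecure"),
        Construct("sociable", "withdrawn"),
    ],
    elements=[
        GridElement("present_self", "how I am"),
        GridElement("self_before_lesion", "how I was before the injury"),
        GridElement("ideal_self", "how I would like to be"),
    ],
    #          present  before  ideal
    ratings=np.array(
        [
            [6, 2, 1],   # happy(1) .. sad(7): present leans sad, ideal happy
            [5, 3, 2],
            [4, 1, 1],
            [7, 2, 1],
            [3, 2, 2],
        ]
    ),
)
assert validate_grid(grid) == []

print("Standardized Euclidean distances (0 = identical, 1 = maximal):")
for pair, d in all_pairwise_distances(grid).items():
    print(f"  {pair.first} vs {pair.second}: {d:.3f}")

print("\nOpposed-pole proportion (fraction of constructs rated 1-3 on one")
print("element and 5-7 on the other):")
for a, b in (
    ("present_self", "self_before_lesion"),
    ("present_self", "ideal_self"),
):
    print(f"  {a} vs {b}: {opposed_pole_proportion(grid, a, b):.2f}")

print("\nPolarization (fraction of ratings at the extremes 1 or 7):")
for role in ("present_self", "self_before_lesion", "ideal_self"):
    print(f"  {role}: {element_polarization(grid, role):.2f}")
print(f"  whole matrix: {total_polarization(grid):.3f}")

print(
    "\nA large present-ideal distance with opposed ratings indicates the "
    "participant sees their current self at the undesirable pole of "
    "constructs where the ideal sits at the desirable pole."
)
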