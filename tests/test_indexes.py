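"""Element distances, opposed-pole proportions and polarization indexes."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rgsc import (
    ElementPair,
    all_pairwise_distances,
    compute_indexes,
    element_polarization,
    euclidean_distance,
    indexes_table,
    opposed_pole_proportion,
    total_polarization,
)
from rgsc.grid import GridElement
from rgsc.indexes import INDEX_COLUMNS

from conftest import make_grid, random_grid

P, B, I = "present_self", "self_before_lesion", "ideal_self"


def naive_ed(grid, a, b):
    """Two-loop reference implementation of the standardized distance."""
    x, y = grid.column(a), grid.column(b)
    total = 0.0
    for xi, yi in zip(x, y):
        total += (float(xi) - float(yi)) ** 2
    return math.sqrt(total) / (grid.scale.max_difference * math.sqrt(grid.n_constructs))


class TestElementPair:
    def test_unordered_equality(self):
        assert ElementPair(P, I) == ElementPair(I, P)
        assert hash(ElementPair(P, I)) == hash(ElementPair(I, P))

    def test_distinct_elements_required(self):
        with pytest.raises(ValueError):
            ElementPair(P, P)


class TestEuclideanDistance:
    @pytest.mark.parametrize("c", [1, 3, 19])
    def test_maximum_distance_is_one(self, c):
        grid = make_grid(np.column_stack([np.ones(c), np.ones(c), np.full(c, 7)]))
        assert euclidean_distance(grid, P, I) == 1.0

    def test_identical_columns_give_zero(self):
        grid = make_grid([[3, 5, 3], [1, 2, 1], [7, 7, 7]])
        assert euclidean_distance(grid, P, I) == 0.0

    def test_hand_worked_example(self):
        # x=(1,4,7), y=(2,2,5): sum of squared diffs = 1+4+4 = 9
        grid = make_grid(np.column_stack([[1, 4, 7], [2, 2, 5], [4, 4, 4]]))
        expected = math.sqrt(9) / (6 * math.sqrt(3))
        assert euclidean_distance(grid, P, B) == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(0.2887, abs=5e-5)

    def test_absent_role_names_the_role(self):
        grid = make_grid([[1, 2, 3]])
        grid.elements = grid.elements[:2]
        grid.ratings = grid.ratings[:, :2]
        with pytest.raises(KeyError, match="ideal_self"):
            euclidean_distance(grid, P, I)

    @given(st.integers(0, 2 ** 31))
    def test_symmetry_and_range(self, seed):
        grid = random_grid(np.random.default_rng(seed))
        d_ab = euclidean_distance(grid, P, I)
        assert euclidean_distance(grid, I, P) == d_ab
        assert 0.0 <= d_ab <= 1.0

    @given(st.integers(0, 2 ** 31), st.integers(2, 5))
    def test_row_duplication_leaves_distance_unchanged(self, seed, k):
        """Stacking k copies of the construct rows cannot change ED: the
        normalization scales with sqrt(C)."""
        grid = random_grid(np.random.default_rng(seed))
        big = make_grid(np.tile(grid.ratings, (k, 1)))
        assert euclidean_distance(big, P, I) == pytest.approx(
            euclidean_distance(grid, P, I), abs=1e-12
        )

    @given(st.integers(0, 2 ** 31))
    def test_matches_naive_oracle(self, seed):
        grid = random_grid(np.random.default_rng(seed))
        for pair in ((P, B), (P, I), (B, I)):
            assert euclidean_distance(grid, *pair) == pytest.approx(
                naive_ed(grid, *pair), abs=1e-12
            )


class TestAllPairwiseDistances:
    def test_three_elements_give_three_pairs(self):
        grid = random_grid(np.random.default_rng(1), c=5, e=3)
        assert len(all_pairwise_distances(grid)) == 3

    def test_four_elements_give_six_pairs(self):
        grid = random_grid(np.random.default_rng(2), c=5, e=4)
        assert len(all_pairwise_distances(grid)) == 6

    def test_entries_match_per_pair_recomputation(self):
        grid = random_grid(np.random.default_rng(3), c=8, e=4)
        for pair, value in all_pairwise_distances(grid).items():
            assert value == euclidean_distance(grid, pair.first, pair.second)


class TestOpposedPoleProportion:
    def test_happy_sad_worked_example(self):
        # present self Very sad (7), self before the lesion Somewhat happy (3)
        grid = make_grid([[7, 3, 4]])
        assert opposed_pole_proportion(grid, P, B) == 1.0

    def test_midpoint_never_counts(self):
        for col in ([4, 7, 1], [7, 4, 1]):
            grid = make_grid([col])
            assert opposed_pole_proportion(grid, P, B) == 0.0

    def test_identical_columns_give_zero(self):
        grid = make_grid([[2, 2, 5], [6, 6, 1]])
        assert opposed_pole_proportion(grid, P, B) == 0.0

    def test_band_check_worked_example(self):
        # constructs 1,2 opposed; 3 blocked by midpoint on x; 4 same side
        x, y = [1, 3, 4, 5], [7, 5, 1, 5]
        grid = make_grid(np.column_stack([x, y, [4] * 4]))
        assert opposed_pole_proportion(grid, P, B) == 0.5

    @given(st.integers(0, 2 ** 31))
    def test_symmetric_and_bounded(self, seed):
        grid = random_grid(np.random.default_rng(seed))
        p_ab = opposed_pole_proportion(grid, P, I)
        assert opposed_pole_proportion(grid, I, P) == p_ab
        assert 0.0 <= p_ab <= 1.0

    @given(st.integers(0, 2 ** 31))
    def test_fully_opposed_forces_distance_above_third(self, seed):
        """If every construct is rated at opposite bands, each rating pair
        differs by at least 2, so ED >= 2/MD = 1/3 on the 1-7 scale."""
        rng = np.random.default_rng(seed)
        c = int(rng.integers(1, 15))
        left = rng.integers(1, 4, size=c)
        right = rng.integers(5, 8, size=c)
        flip = rng.uniform(size=c) < 0.5
        x = np.where(flip, left, right)
        y = np.where(flip, right, left)
        grid = make_grid(np.column_stack([x, y, np.full(c, 4)]))
        assert opposed_pole_proportion(grid, P, B) == 1.0
        assert euclidean_distance(grid, P, B) >= 1.0 / 3.0 - 1e-12


class TestPolarization:
    def test_no_extremes(self):
        grid = make_grid(np.full((4, 3), 4))
        assert element_polarization(grid, P) == 0.0
        assert total_polarization(grid) == 0.0

    def test_all_extremes(self):
        grid = make_grid(np.column_stack([[1, 7, 1], [7, 7, 1], [1, 1, 7]]))
        assert element_polarization(grid, P) == 1.0
        assert total_polarization(grid) == 1.0

    def test_direct_count_example(self):
        grid = make_grid(np.column_stack([[1, 7, 4, 5, 2], [4] * 5, [4] * 5]))
        assert element_polarization(grid, P) == pytest.approx(0.4)

    def test_all_ones_matrix(self):
        assert total_polarization(make_grid(np.ones((6, 3)))) == 1.0

    def test_total_equals_mean_of_elements(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            grid = random_grid(rng)
            per_element = [element_polarization(grid, r) for r in (P, B, I)]
            assert total_polarization(grid) == pytest.approx(
                np.mean(per_element), abs=1e-12
            )


class TestIndexSet:
    def test_construct_order_never_matters(self):
        rng = np.random.default_rng(7)
        grid = random_grid(rng, c=12)
        perm = rng.permutation(12)
        shuffled = make_grid(grid.ratings[perm])
        a, b = compute_indexes(grid), compute_indexes(shuffled)
        assert a.distances == b.distances
        assert a.opposed_proportions == b.opposed_proportions
        assert a.element_polarization == b.element_polarization
        assert a.total_polarization == b.total_polarization

    def test_tidy_table_layout(self):
        rng = np.random.default_rng(8)
        sets = [compute_indexes(random_grid(rng, pid=f"p{k}")) for k in range(4)]
        table = indexes_table(sets)
        assert list(table.columns) == INDEX_COLUMNS
        assert len(table) == 4
        assert table["ed_present_ideal"].between(0, 1).all()

    def test_other_elements_keyed_by_label(self):
        grid = random_grid(np.random.default_rng(9), c=4, e=5)
        keys = {e.key() for e in grid.elements}
        assert {"other:other 0", "other:other 1"} <= keys
        assert len(all_pairwise_distances(grid)) == 10
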