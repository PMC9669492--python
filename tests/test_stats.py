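"""Rank correlation, p-values, bootstrap CIs and interval overlap."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, special, stats as sps

from rgsc import (
    MeanWithCI,
    bootstrap_ci,
    bootstrap_mean,
    cis_overlap,
    correlate,
    spearman_p,
    spearman_rho,
)
from rgsc.stats import DegenerateDataError, spearman_p_exact, stars


def rank_then_pearson(x, y):
    """Independent two-step oracle: assign average ranks by sorting, then
    Pearson by its closed form."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestSpearmanRho:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_perfect_reversal(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_tied_data_matches_two_step_oracle(self):
        x, y = [1, 1, 2, 3], [2, 1, 4, 4]
        assert spearman_rho(x, y) == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    @given(st.integers(0, 2 ** 31), st.integers(4, 30))
    def test_matches_scipy_cross_check(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, n).astype(float)
        try:
            ours = spearman_rho(x, y)
        except DegenerateDataError:
            assert len(set(x)) == 1 or len(set(y)) == 1
            return
        ref = sps.spearmanr(x, y).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 2 ** 31))
    def test_invariant_under_strict_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, y ** 3) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(2 * x + 7, np.arctan(y)) == pytest.approx(base, abs=1e-12)

    def test_degenerate_input_signalled(self):
        with pytest.raises(DegenerateDataError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 2, np.nan], [3, 4, 5])


class TestSpearmanP:
    def test_zero_rho_gives_one(self):
        assert spearman_p(0.0, 33) == 1.0

    def test_unit_rho_convention(self):
        assert spearman_p(1.0, 33) == 0.0
        assert spearman_p(-1.0, 10) == 0.0

    def test_against_numerical_integration_oracle(self):
        """Two-sided p from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df, with the
        tail mass obtained by integrating the t density directly."""
        rho, n = 0.5, 33
        df = n - 2
        t = rho * math.sqrt(df / (1 - rho ** 2))

        def t_pdf(u):
            c = special.gamma((df + 1) / 2) / (
                math.sqrt(df * math.pi) * special.gamma(df / 2)
            )
            return c * (1 + u * u / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(t_pdf, t, np.inf)
        assert spearman_p(rho, n) == pytest.approx(2 * tail, rel=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_p(0.5, 3)

    def test_exact_permutation_small_sample(self):
        x = [1.0, 2, 3, 4, 5, 6]
        y = [2.0, 1, 4, 3, 6, 5]
        p = spearman_p_exact(x, y)
        assert 0.0 < p <= 1.0
        # perfectly monotone data: only the 2 extreme orderings tie the stat
        assert spearman_p_exact(x, sorted(y)) == pytest.approx(2 / math.factorial(6))
        with pytest.raises(ValueError):
            spearman_p_exact(list(range(9)), list(range(9)))


class TestBootstrapCI:
    def test_monotone_data_degenerate_interval(self):
        x = np.arange(10.0)
        est, lo, hi = bootstrap_ci(x, 2 * x + 1, n_boot=200, seed=3)
        assert (est, lo, hi) == (1.0, 1.0, 1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = bootstrap_ci(x, y, n_boot=300, seed=11)
        b = bootstrap_ci(x, y, n_boot=300, seed=11)
        assert a == b
        c = bootstrap_ci(x, y, n_boot=300, seed=12)
        assert a != c

    def test_pathological_input_reports_degeneracy(self):
        x = np.ones(8)
        with pytest.raises(DegenerateDataError):
            bootstrap_ci(x, np.arange(8.0), n_boot=10, seed=0)

    def test_interval_ordered_and_bounded(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=25), rng.normal(size=25)
        est, lo, hi = bootstrap_ci(x, y, n_boot=500, seed=1)
        assert -1.0 <= lo <= hi <= 1.0

    def test_bca_variant(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        est, lo, hi = bootstrap_ci(x, y, n_boot=500, seed=2, method="bca")
        assert -1.0 <= lo < hi <= 1.0
        with pytest.raises(ValueError):
            bootstrap_ci(x, y, method="percentile2", seed=0)

    def test_width_shrinks_with_n(self):
        """Median CI width over repeated datasets falls as n grows."""
        from rgsc import simulate_rank_pairs

        widths = {}
        for n in (20, 200):
            w = []
            for rep in range(12):
                x, y = simulate_rank_pairs(n, 0.4, seed=100 + rep)
                _, lo, hi = bootstrap_ci(x, y, n_boot=300, seed=rep)
                w.append(hi - lo)
            widths[n] = np.median(w)
        assert widths[200] < widths[20]


class TestBootstrapMean:
    def test_constant_vector_zero_width(self):
        m = bootstrap_mean(np.full(12, 3.5), n_boot=200, seed=1)
        assert (m.mean, m.ci_low, m.ci_high) == (3.5, 3.5, 3.5)

    def test_deterministic(self):
        x = np.random.default_rng(8).normal(size=33)
        assert bootstrap_mean(x, seed=4) == bootstrap_mean(x, seed=4)

    def test_width_tracks_clt(self):
        """At n=33 the percentile interval width should approximate the
        normal-theory width 2 * 1.96 * sigma / sqrt(n)."""
        widths = []
        for s in range(100):
            x = np.random.default_rng(1000 + s).standard_normal(33)
            m = bootstrap_mean(x, n_boot=500, seed=s)
            widths.append(m.ci_high - m.ci_low)
        expected = 2 * 1.96 / math.sqrt(33)
        assert abs(np.mean(widths) - expected) / expected < 0.25


class TestOverlapAndStars:
    def _mk(self, lo, hi):
        return MeanWithCI((lo + hi) / 2, lo, hi, 33, 1000, 0)

    def test_reported_distance_intervals_overlap(self):
        assert cis_overlap(self._mk(0.31, 0.47), self._mk(0.29, 0.43))

    def test_disjoint_intervals(self):
        assert not cis_overlap(self._mk(0.0, 1.0), self._mk(2.0, 3.0))

    def test_touching_endpoints_count(self):
        assert cis_overlap(self._mk(0.0, 1.0), self._mk(1.0, 2.0))

    @pytest.mark.parametrize(
        "p, expected",
        [(0.0004, "***"), (0.004, "**"), (0.04, "*"), (0.2, ""), (0.05, "")],
    )
    def test_star_convention(self, p, expected):
        assert stars(p) == expected


class TestCorrelate:
    def test_cell_contents(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=33)
        y = x + rng.normal(size=33)
        cell = correlate(x, y, n_boot=300, seed=21)
        assert cell.n == 33 and cell.n_boot == 300 and cell.seed == 21
        assert cell.ci_low <= cell.rho <= cell.ci_high
        assert cell.p_value == spearman_p(cell.rho, 33)
        assert cell.stars == stars(cell.p_value)
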