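"""Spearman correlations with non-parametric bootstrap confidence intervals.

The association machinery used throughout the analysis: Spearman's rho
(average ranks for ties, then Pearson on the ranks), a two-sided p-value
from the t approximation, percentile bootstrap confidence intervals formed
by resampling participants (paired observations) with replacement, and the
interval-overlap comparison used to contrast mean element distances.

Everything that consumes randomness takes an explicit ``seed`` and is a pure
function of its inputs: same data, same seed, same number of resamples give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DegenerateDataError",
    "CorrelationCell",
    "MeanWithCI",
    "spearman_rho",
    "spearman_p",
    "spearman_p_exact",
    "bootstrap_ci",
    "bootstrap_mean",
    "correlate",
    "cis_overlap",
    "stars",
]


class DegenerateDataError(ValueError):
    """A statistic is undefined on the given data (e.g. zero rank variance)."""


def stars(p: float) -> str:
    """Significance stars: ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationCell:
    """One correlation-table cell: rho with percentile bootstrap CI and
    t-approximation p-value.  Stored at full precision; 2-decimal rounding
    happens only at report rendering."""

    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_boot: int
    seed: int

    @property
    def stars(self) -> str:
        return stars(self.p_value)


@dataclass(frozen=True)
class MeanWithCI:
    mean: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks.

    Raises :class:`DegenerateDataError` when either vector has zero rank
    variance (all values tied), where rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = np.sqrt((rx @ rx) * (ry @ ry))
    if den == 0:
        raise DegenerateDataError("zero rank variance: rho undefined")
    return float(np.clip((rx @ ry) / den, -1.0, 1.0))


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p-value for Spearman's rho via the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of freedom.

    ``|rho| = 1`` maps to p = 0 by convention.
    """
    if n < 4:
        raise ValueError(f"t approximation requires n >= 4, got {n}")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho={rho} outside [-1, 1]")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman_p_exact(x, y) -> float:
    """Exact two-sided permutation p-value for Spearman's rho (small n).

    Enumerates all n! permutations of y, so it is restricted to n <= 8;
    intended as a small-sample alternative to the t approximation.
    """
    from itertools import permutations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact permutation p restricted to n <= 8")
    obs = abs(spearman_rho(x, y))
    ry = sps.rankdata(y)
    count = total = 0
    for perm in permutations(range(n)):
        r = spearman_rho(x, ry[list(perm)])
        total += 1
        if abs(r) >= obs - 1e-12:
            count += 1
    return count / total


def _percentile_interval(samples: np.ndarray, level: float):
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_ci(
    x,
    y,
    statistic=spearman_rho,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
    method: str = "percentile",
):
    """Non-parametric bootstrap CI for a paired statistic.

    Participant pairs ``(x_j, y_j)`` are resampled jointly with replacement
    ``n_boot`` times; the interval is the percentile interval of the
    bootstrap distribution (or the bias-corrected-and-accelerated interval
    with ``method="bca"``).  A resample on which the statistic is undefined
    (:class:`DegenerateDataError`) is redrawn, up to 100 * n_boot total
    attempts; pathological inputs that exhaust the cap raise with the
    observed degeneracy rate.

    Returns ``(estimate, ci_low, ci_high)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if method not in ("percentile", "bca"):
        raise ValueError(f"unknown CI method {method!r}")
    estimate = statistic(x, y)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_boot)
    attempts = 0
    cap = 100 * n_boot
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            attempts += 1
            try:
                samples[b] = statistic(x[idx], y[idx])
                break
            except DegenerateDataError:
                if attempts >= cap:
                    raise DegenerateDataError(
                        f"bootstrap degenerate: {attempts - b} of {attempts} "
                        f"resamples had an undefined statistic"
                    ) from None

    if method == "percentile":
        lo, hi = _percentile_interval(samples, level)
    else:
        lo, hi = _bca_interval(x, y, statistic, estimate, samples, level)
    return float(estimate), lo, hi


def _bca_interval(x, y, statistic, estimate, samples, level):
    # bias correction from the bootstrap distribution, acceleration from the
    # jackknife; falls back to percentile bounds when degenerate
    n = x.size
    prop = np.mean(samples < estimate)
    if prop in (0.0, 1.0):
        return _percentile_interval(samples, level)
    z0 = sps.norm.ppf(prop)
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[j] = False
        try:
            jack[j] = statistic(x[mask], y[mask])
        except DegenerateDataError:
            jack[j] = estimate
        mask[j] = True
    d = jack.mean() - jack
    denom = (d @ d) ** 1.5
    a = (d**3).sum() / (6.0 * denom) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        zq = z0 + sps.norm.ppf(q)
        adj = sps.norm.cdf(z0 + zq / (1.0 - a * zq))
        out.append(float(np.quantile(samples, adj)))
    return out[0], out[1]


def bootstrap_mean(
    x, n_boot: int = 1000, level: float = 0.95, seed: int | np.random.SeedSequence = 0
) -> MeanWithCI:
    """Percentile bootstrap CI for an arithmetic mean (resampling the
    observations with replacement)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = _percentile_interval(means, level)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return MeanWithCI(float(x.mean()), lo, hi, x.size, n_boot, int(seed_int))


def correlate(
    x,
    y,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    method: str = "percentile",
) -> CorrelationCell:
    """Spearman rho with bootstrap CI and t-approximation p-value, packaged
    as one correlation-table cell."""
    rho, lo, hi = bootstrap_ci(
        x, y, spearman_rho, n_boot=n_boot, level=level, seed=seed, method=method
    )
    n = np.asarray(x).size
    return CorrelationCell(rho, lo, hi, spearman_p(rho, n), n, n_boot, int(seed))


def cis_overlap(a: MeanWithCI, b: MeanWithCI) -> bool:
    """True iff the two confidence intervals share at least one point
    (touching endpoints count as overlap)."""
    return max(a.ci_low, b.ci_low) <= min(a.ci_high, b.ci_high)
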