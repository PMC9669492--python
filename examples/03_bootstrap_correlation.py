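"""Spearman correlation with a percentile bootstrap confidence interval.

Draws a bivariate sample with known population rank correlation 0.5 from a
Gaussian copula, then estimates rho with a 95% CI obtained by resampling
the paired observations with replacement.
"""

from rgsc import correlate, simulate_rank_pairs

x, y = simulate_rank_pairs(n=33, true_rho=0.5, seed=7)
cell = correlate(x, y, n_boot=1000, level=0.95, seed=11)

print(f"n = {cell.n}, bootstrap resamples = {cell.n_boot}")
print(
    f"rho = {cell.rho:.2f} [{cell.ci_low:.2f}, {cell.ci_high:.2f}]"
    f"{cell.stars}  (p = {cell.p_value:.4f})"
)
print(
    "\nThe interval is the 2.5th-97.5th percentile band of the bootstrap "
    "distribution; with a true rank correlation of 0.5 it should cover 0.5 "
    "in about 95% of replicate samples of this size."
)
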