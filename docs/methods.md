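# Methods

## Grids and indexes

A repertory grid is a `C × E` integer matrix: `C` bipolar constructs
(rows) rated for `E` elements (columns) on a 7-point Likert scale in which
1–3 lean to the left pole, 4 is the midpoint and 5–7 lean to the right
pole.  The analyses use three elements — present self, self before the
lesion, ideal self — but the types admit additional labelled elements.
Grids with missing cells are rejected at validation rather than imputed:
every index below assumes complete columns, and silent imputation would
change their meaning.

The standardized Euclidean distance between elements `x` and `y`,

    ED(x, y) = sqrt( Σᵢ (xᵢ − yᵢ)² ) / ( MD · √C ),   MD = max − min = 6,

is computed as `sqrt(Σd²/(MD²·C))` — algebraically identical, but keeping
the division inside the square root makes the maximal case (every construct
at opposite extremes) return exactly 1.0 in floating point.  Distances are
computed for all unordered element pairs (three for the standard grid).

The opposed-pole proportion counts constructs with one rating in {1, 2, 3}
and the other in {5, 6, 7}; a midpoint rating on either element excludes
the construct, which is forced by the band definition.  Polarization counts
strict extremes only (exactly 1 or 7).  Total polarization over the matrix
equals the equal-weight mean of the per-element polarizations because every
column has the same number of cells; a test asserts this identity on random
grids.  All indexes are kept at full floating precision; two-decimal
rounding happens only in report rendering.

## Instrument scoring

PHQ-9 and GAD-7 items are 0–3; SWLS items 1–7; QOLIBRI items 1–5.  Totals
are plain sums.  PHQ-9 severity bands open at 5/10/15/20.  The binary
depression split used for cohort description is < 10 vs ≥ 10
(mild vs moderate-to-severe), with the parallel split for the GAD-7; 10 is
the conventional "moderate" cutoff and the most parsimonious reading of a
two-category severity summary.  The published SWLS band list overlaps at 25
and omits 30; we use the standard contiguous bands 21–25 / 26–30 / 31–35.
The QOLIBRI 0–100 score is the linear min-max transform fixed by its
anchors (raw 37 → 0, raw 185 → 100); scaled scores < 60 flag low/impaired
health-related quality of life.  Scorers fail fast on wrong item counts or
out-of-range responses, naming the item.  `cronbach_alpha` is provided as
an internal-consistency utility (undefined — NaN — when the total-score
variance is zero).

## Correlations and bootstrap

Spearman's rho is the Pearson correlation of average ranks (the
conventional tie policy).  Confidence intervals are non-parametric
percentile bootstrap: participant pairs `(xⱼ, yⱼ)` are resampled jointly
with replacement `n_boot` times (default 1,000 — standard for percentile
intervals and fast at n ≈ 33) and the interval is the 2.5th–97.5th
percentile band.  The percentile method is the default as the plainest
reading of "bootstrapped 95% CI"; a bias-corrected-and-accelerated (BCa)
variant is available via `method="bca"`.  A resample on which rho is
undefined (zero rank variance) is redrawn, up to 100·n_boot total
attempts; inputs that exhaust the cap raise with the observed degeneracy
rate, so pathological data surface instead of silently biasing the
interval.  Two-sided p-values use the t approximation
`t = ρ·sqrt((n−2)/(1−ρ²))` on `n − 2` degrees of freedom, standard at this
sample size, with `|ρ| = 1 → p = 0` by convention; an exact permutation
p-value exists for n ≤ 8.  Significance stars follow the usual
convention (* p < 0.05, ** p < 0.01, *** p < 0.001).  No multiple-testing
adjustment is applied by default — mirroring common practice in exploratory
grid studies — but Benjamini–Hochberg within each table is available behind
`adjust_p=True`.

Mean distances are compared descriptively by interval overlap
(`cis_overlap`, endpoints inclusive): overlapping 95% CIs are read as no
evidence of a difference.

## Synthetic cohorts

The generator emulates the structure of a 33-participant post-injury
cohort; it is the test bed for every downstream stage, not a model of any
real dataset.  Per participant:

* construct count `C ~ round(Normal(19, 3.9))`, floored at 5 — matching
  the reported mean and SD of elicited constructs;
* latent distress `d ~ Uniform(0, 1)`.  Uniform rather than normal because
  only the rank structure matters to Spearman statistics, and uniform makes
  the copula algebra transparent;
* each construct gets a random desirable pole; the ideal self is rated at
  the desirable extreme with probability `p_polar_ideal = 0.55` (matching a
  mean ideal-self polarization of 0.55), else one step in;
* the pre-injury self is the ideal nudged toward — occasionally past — the
  midpoint by a geometric number of steps (mean `noise_sd = 1`); allowing
  crossings gives the pre-injury/ideal contrast realistic variance;
* the present self drifts from the pre-injury self toward the undesirable
  pole by `round(5·d)` steps plus symmetric geometric jitter, clipped to
  the scale.  Five steps at maximal distress spans most of the scale
  without saturating the clip.

Questionnaire totals are monotone images of an instrument-specific latent
`z = ±(r·z_d + sqrt(1−r²)·ε)` (positive sign for PHQ-9/GAD-7, negative for
SWLS/QOLIBRI), where `z_d` is the normal score of `d`.  The mixing weight
`r` is chosen so that the realized Spearman correlation between
ED(present, ideal) and the PHQ-9 total equals `target_rho`: rank and
Pearson correlations relate by `ρ_rank = (6/π)·arcsin(r/2)` under the
Gaussian copula, and the attenuation introduced by finite grids, rating
jitter and item discretization was measured once at n = 50,000 and frozen
as a constant (0.9380).  Item responses distribute the total across items
with a random remainder assignment, so per-item patterns vary while the
total stays exactly monotone in the latent.

One master seed expands into per-participant substreams via
`SeedSequence.spawn`, so enlarging a cohort never changes earlier
participants' data.

What the generator does **not** emulate: real construct semantics, item
factor structure (items within an instrument are exchangeable here),
missing data, demographic covariates, GOAT time courses, or severity
strata.  Passing recovery tests therefore show that the pipeline measures
what the generator encodes — not that any particular clinical effect size
is correct.

## Problem sizes and numerical choices

The test suite exercises: oracle equivalence of the distance formula on
1,000 random grids (tolerance 1e-12); bootstrap CI coverage at n = 33 and
true rank correlation 0.5 over 200 replicate datasets with 1,000 resamples
each (expected coverage ≥ 0.90); and link recovery on 20 cohorts of 200
participants per target (median within ±0.15 of 0.5, monotone across
targets 0 → 0.3 → 0.6).  These sizes give stable Monte-Carlo estimates
while keeping the full suite in the low minutes on one CPU.  The packaged
example cohort (33 participants, seed 20180101) is synthetic, generated by
this module, and is the determinism anchor: the analysis on it is
byte-stable and checked against a stored reference report at 1e-9.

Report serialization writes floats with `%.17g` (CSV) or full JSON
precision, and parsing uses round-trip float handling, so rendered machine
tables reparse to bit-identical cells.

## Known limitations

* The t-approximation p-value is approximate under heavy ties at small n.
* Percentile intervals for strong correlations at n ≈ 33 are conservative
  (observed coverage ~0.98 at ρ = 0.5); BCa narrows them slightly.
* `target_rho` above ~0.94 is not reachable: the copula weight saturates at
  the measured attenuation ceiling.
* Cronbach's alpha is a utility only; the generator's exchangeable items
  make it uninformative about real instruments.
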