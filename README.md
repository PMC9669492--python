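# rgsc — quantitative repertory-grid self-concept analysis

`rgsc` implements the quantitative arm of repertory-grid studies of
self-concept after acquired brain injury: grid-derived self-discrepancy and
polarization indexes, clinical questionnaire scoring, and Spearman
correlation tables with non-parametric bootstrap confidence intervals.  It
is written for clinical researchers who collect repertory grids (elements:
*present self*, *self before the lesion*, *ideal self*; constructs rated on
a 7-point Likert scale) together with the PHQ-9, GAD-7, SWLS and QOLIBRI,
and want a reproducible, scriptable pipeline from raw tables to the final
correlation tables.

## The indexes

For two elements `x` and `y` rated on `C` bipolar constructs, the
standardized Euclidean distance is

    ED(x, y) = sqrt( Σᵢ (xᵢ − yᵢ)² ) / ( MD · √C )

with `MD = 6` the maximum rating difference on the 1–7 scale, so
`ED ∈ [0, 1]` and 1 is the maximal possible self-discrepancy.  Two further
families quantify *how* elements differ:

* **opposed-pole proportion** — the fraction of constructs rated in the
  left band (1–3) on one element and the right band (5–7) on the other
  (a midpoint 4 never counts);
* **polarization** — the fraction of ratings at the exact extremes (1 or
  7), per element and over the whole matrix, an index of rigid or extreme
  construing.

Instrument totals follow the published scoring rules (PHQ-9 bands at
5/10/15/20; SWLS bands with 20 the neutral point; QOLIBRI raw 37–185
rescaled linearly to 0–100 with scores < 60 flagging impaired quality of
life).  Associations are Spearman rank correlations; each is reported with
a 95% percentile bootstrap CI (participants resampled in pairs with
replacement) and a two-sided p-value from the t approximation.

Because no clinical data ship with the package, a synthetic-cohort
generator produces grids and item responses with a *known* latent distress
structure, so the whole pipeline — including how well it recovers a
configured distance–symptom rank correlation — is testable end to end.

## Worked example

Correlating a sample with a known population rank correlation of 0.5
(`examples/03_bootstrap_correlation.py`):

```python
from rgsc import correlate, simulate_rank_pairs

x, y = simulate_rank_pairs(n=33, true_rho=0.5, seed=7)
cell = correlate(x, y, n_boot=1000, level=0.95, seed=11)
```

prints

```
n = 33, bootstrap resamples = 1000
rho = 0.54 [0.23, 0.78]**  (p = 0.0011)
```

i.e. the estimated rank correlation is 0.54, the percentile bootstrap 95%
interval is [0.23, 0.78] (covering the true value 0.5), and the two stars
flag p < 0.01.  The full pipeline on the packaged synthetic cohort
(`examples/05_full_analysis.py`) prints descriptives, mean element
distances with CIs, and the four correlation tables; its first distance
rows read

```
Mean element distances:
  Present self - self before the lesion: 0.38 [0.32, 0.44]
  Present self - ideal self: 0.54 [0.48, 0.60]
```

meaning the simulated participants sit, on average, at 38% of the maximal
possible discrepancy from their pre-injury self and 54% from their ideal
self.

The same pipeline is available from the shell:

```sh
rgsc simulate --n 33 --seed 1 -o cohort/
rgsc validate cohort/
rgsc analyze cohort/ cohort/measures.csv --n-boot 1000 --seed 1 -o report/
```

`examples/` contains one short narrative script per capability.

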