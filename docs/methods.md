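# Methods

## The analysis model

`pbarray` models a two-species, two-tissue, two-treatment microarray
experiment on a single array design. The sensitive model species is the
array's native species; the tolerant accumulator is hybridized to the same
array (cross-species hybridization, CSH). Sequence divergence means some
probes never bind the non-native species' transcripts; those probes carry
only background-level signal and must be removed before testing, which the
background-retention rule does as a side effect of its stated purpose
(discarding unexpressed probes).

### Normalization

Between-array variation is removed by upper-quartile scaling: each array is
multiplied by a constant so that its 75th-percentile intensity equals the
geometric mean of all arrays' 75th percentiles. Percentiles use linear
interpolation between order statistics. The transform is a pure rescaling
(within-array ratios are preserved) and is idempotent. A classic full
quantile-normalization mode (`normalization_mode: quantile`) is provided
for sensitivity checks; it forces identical marginal distributions and is
deliberately not the default, since the upper-quartile variant is the
percentile-shift scaling standard for single-channel arrays of this type.

Each probe is then divided by its median across **all** samples (median
centering), putting every probe on a common relative scale. Intensities
are log₂ for testing; fold changes are always reported linear.

**Stage order.** The background filter runs on the between-array-normalized
intensities, *before* median centering. The floor is an absolute intensity
value; after per-probe centering every probe has median 1 and an absolute
floor is meaningless. Because centering divides a probe's control and
treated values by the same constant, the *t* statistic and the fold-change
ratio are unchanged by the reordering; only the filter needs the intensity
scale.

### Differential expression

Per species × tissue contrast, retained probes are collapsed to genes
(when several probes map to one gene, the probe with the largest mean
intensity across all samples represents it) and tested with a two-sided
pooled-variance Student *t*-test on log₂ values — the "asymptotic"
*t*-distribution p-value, vectorized across genes. Zero pooled variance
with equal means yields p = 1; with unequal means p = 0 and a
`zero_variance` flag (the statistic is degenerate there; on continuous
synthetic data this cannot occur). Benjamini–Hochberg adjustment is applied
across all genes tested within the contrast, and a gene is *regulated* iff
q < 0.1 (the FDR call; the raw p < 0.05 level is exposed as `p_threshold`
but is the pre-correction test level, not an additional filter). Fold
change is the ratio of linear-scale condition means.

### Candidate cascade

Within a tissue, the gene universe is the intersection of genes tested in
both species — a gene not surviving background filtering in one species
cannot be classified as common. Regulated genes partition into
Pb-specific (one species) and Pb-common (both, with a sign pair; first
sign = tolerant species). Thresholds are strict: FC > 2.0 or FC < 0.5;
boundary values are discarded. The cross-species ratio filter divides
linear fold changes regardless of direction agreement, so an opposite-sign
gene can pass on ratio alone. Counts are conserved at every stage
(input = retained + discarded), and candidates are direction-partitioned,
so candidate totals equal up + down sums.

Note on published accounting of this design: the shoot-specific retained
counts printed in the selection table sum to 330 while the accompanying
text says 331 (and the specific totals appear once as 602 and once as 601);
the pipeline always reports computed sums, so the tabulated 330/601 side is
what it reproduces.

### Enrichment

The class score is the normed frequency: the class's share of the
classified input list divided by its share of the classified reference
list. Genes may belong to several classes; unclassified genes leave both
denominators. The reference defaults to every classified gene on the
array. Stability: B = 100 bootstrap resamples of the input list (with
replacement, original size; duplicated genes count multiply in numerator
and denominator), reporting the resample mean and the standard deviation
of the B scores as the bootstrap SE — an exactly resample-invariant class
gets SE = 0. Significance is a two-sided hypergeometric (Fisher-exact
one-cell) test: p sums the pmf over all counts whose probability does not
exceed the observed count's. No multiple-testing correction across classes
by default (`bh_correct` is available). Classes with fewer than 5 input
genes are flagged `o`; significant classes (p < α = 0.05) are flagged `*`.
The flag convention's source display prints the significance condition
with the inequality inverted; it is implemented as p < α.

### Concordance

Array and qRT-PCR fold changes are compared as Pearson correlation of
log₁₀ values, pooling tissues (per-tissue values are reported alongside).
Pairs missing a value in either assay are dropped with a logged count;
zero variance in either coordinate leaves r undefined (reported missing).

## Synthetic data generator

The generator emulates the study design: 2 species × 2 tissues ×
(control, Pb) × 3 replicates. Defaults, chosen once as typical for
single-channel arrays of this class:

| parameter | default | meaning |
|---|---|---|
| `base_log2_mean`, `base_log2_sd` | 10, 1.5 | per-gene log-normal base expression (shared across species/tissues) |
| `fc_planted` | 4.0 | linear fold change applied to treated replicates of planted genes (up ×4, down ×¼) |
| `noise_sd` | 0.2 | replicate noise sd, log₂ scale |
| `array_scale_sd` | 0.1 | per-array multiplicative jitter sd, log₂ scale (removed by quartile normalization) |
| `background` | 50 | intensity floor used by the retention rule |
| `dropout_rate` | 0.2 | fraction of probes silenced for the tolerant species — uniform signal in (0, background], the CSH failure surrogate |
| `n_replicates` | 3 | arrays per condition |
| `common_fraction` | 0.0 | fraction of planted genes also regulated in the sensitive species |

Planted genes respond in the tolerant species only by default, making them
Pb-specific and hence recoverable by the full cascade; `common_fraction`
plants a subset in both species with the same fold change, and those are
correctly removed by the ratio filter (ratio ≈ 1) — useful for testing the
filter, not for recovery scoring. Dropped probes are drawn only from
non-planted genes (a planted-but-invisible gene would make recovery
undefined), and one probe maps to one gene unless `n_probes > n_genes`, in
which case extra probes land on random genes and the max-mean collapse rule
is exercised. All randomness flows through a single `numpy` generator
seeded from `seed`; a fixed config reproduces byte-identical TSV output.

What the generator does **not** emulate: sequence-level divergence (dropout
is a per-probe Bernoulli surrogate), intensity-dependent (loess-type) dye
or saturation effects, correlated noise between genes, probe-level GC or
affinity bias, and partial hybridization (a probe either works or is at
background). Passing recovery tests therefore demonstrates the pipeline's
statistical behaviour under a clean log-normal error model, not performance
on arrays with structured artifacts.

The simulated qRT-PCR panel draws genes from the regulated rows of a DE
table and sets log₁₀ FC_qPCR = log₁₀ FC_array + N(0, noise_sd): assay
noise only, no amplification-efficiency or primer effects.

## Numerical choices and edge cases

- Percentile rule: linear interpolation (`numpy.quantile` default); on
  continuous synthetic data ties do not arise.
- BH adjustment via `statsmodels`; the test suite checks it against a
  literal step-up double loop.
- Hypergeometric p-values use a relative tie tolerance of 1e-12 when
  summing "as or less probable" terms, so float-equal pmf values on both
  tails are counted as ties (the test suite verifies exact agreement with
  `math.comb` summation for every configuration with reference ≤ 60).
- Bootstrap resamples with zero classified genes contribute no score; a
  class absent from the reference is reported missing (NaN).
- Probe collapse ties (equal mean intensity) resolve to the first probe in
  a stable sort — deterministic, and measure-zero on continuous data.
- Empty candidate lists propagate as empty tables, not errors.
- Serialization: 6 significant digits for intensities/FCs, scientific
  notation for p/q; LF and CRLF inputs both accepted.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use simulations of 1,000 genes:
50 independent null experiments for type-I calibration (the observed
raw-p < 0.05 fraction is compared to 0.05 within 3 Monte-Carlo standard
errors, computed from the between-run spread since genes within a run share
normalization estimates), 10 seeded experiments with 100 planted genes each
for cascade recovery (recovery ≥ 80%, observed false-discovery proportion
≤ 0.2 at the default thresholds), and B = 10,000 resamples for bootstrap
convergence (within 2% of the exact statistic on a 50-gene list). These
sizes give stable statistics while keeping a full run in seconds on one
core.

## Known limitations

- "Quartile normalization" is interpreted as upper-quartile percentile
  scaling; if the original processing meant full quantile normalization,
  absolute DE counts would shift (the `quantile` mode exists to check).
- The enrichment significance test is a design choice: the class-score
  tool this module mirrors publishes bootstrap scores without stating its
  test, so the hypergeometric test here is principled but not a
  reproduction.
- Reproducing the published r² = 0.92 array/qPCR concordance requires the
  original validation fold-change table, which ships with the study's
  supplementary material, not with this package; the concordance module is
  verified against closed-form oracles and synthetic panels instead.
- No GEO/SOFT importer: inputs are plain TSV matrices plus a sample sheet.
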