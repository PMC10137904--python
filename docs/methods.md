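# Methods

## Model and assumptions

The polish treats an abundance matrix as multiplicatively decomposable:
in log2, an observed value is a feature level, plus a feature x batch
offset (the batch effect), plus a per-sample loading offset, plus
residual signal and noise. Correction alternates two robust centerings:

1. a **row-wise ratio step** dividing each value by a per-(row, batch)
   denominator median and applying the second-term factor
   `grand(i)/M(i, k)`;
2. a **column centering** subtracting each sample's median log2 ratio;

followed by restoration of each row to its input median abundance, and
iteration to convergence. Because both steps are medians, the correction
tolerates outlier samples and outlier features; because the second step
leverages the orders-of-magnitude inter-feature dynamic range, the input
must retain that range (data scaled per-row to a common maximum, for
example, has no meaningful sample-wise central tendency and is not
suitable). Missing values must be missing roughly at random and below
50% per row, so that every median used is a real central tendency.

The three denominator tunings assume, respectively: trait-balanced
batches (`noGIS` — any systematic group difference in a batch median
would be removed with the batch effect); trustworthy pooled standards
(`gis_only`); or standards that exist but may be defective
(`gis_plus_nonGIS`, reference name `useAllNonGIS`). In the last mode the
GIS median cancels algebraically from the product of the two terms, so a
per-batch GIS defect cannot propagate — the effective recentering set is
the non-GIS median. Any systematic whole-sample concentration difference
(e.g. by diagnosis) is removed by design and cannot be recovered
downstream.

## What the iteration converges to

At a fixed point, each row's intra-batch denominator-set (effective:
non-GIS in `useAllNonGIS` mode) medians are equalized across batches up
to a single row-independent per-batch factor, absorbed by batchwise-
constant column-centering offsets; every sample's median log2 ratio to
the restored row medians is exactly 0. Two consequences are worth
knowing:

* **Batch means are over-equalized.** Once batch *medians* are equal,
  the residual between-batch dispersion of batch *means* is the
  mean-median gap of the within-batch residuals, whose variance
  (~0.04 sigma^2 at 8 samples/batch) is *smaller* than the sampling
  variance a one-way ANOVA expects; the truncated method-of-moments
  batch fraction therefore reads 0 for essentially every feature after
  correction.
* **The convergence statistic is a norm difference, not a state
  difference.** Following the printed definition, iteration stops when
  successive Frobenius norms of the working log2 matrix agree within the
  tolerance (default 1e-8). A stricter `||A_t - A_{t-1}||_F` variant is
  available via `convergence="delta_norm"`. With denominator sets of odd
  size the polish can enter a two-cycle (the median is then a single
  order statistic); even set sizes converge deeply in practice, and
  non-convergence at the iteration cap is reported as a warning — treat
  such a run as preliminary.

## Exact algebraic structure

The corrected matrix equals `2^(C*) * m` row-wise, where `C*` is a
fixed point of the centering map and `m` the input row medians saved
before the first ratio step. Hence:

* scaling input row *i* by *c* scales output row *i* by exactly *c*
  (medians are scale-equivariant);
* scaling an input *column* leaves `C*` unchanged but can move any row's
  saved median whose central order statistics are crossed; the output is
  invariant only after compensating by the ratio of saved medians (the
  compensated identity holds to ~1e-11 and is property-tested). Loading
  differences are thus fully removed from the corrected *structure*,
  while the row-scale anchors inherit the input's median robustness —
  exact column-scale invariance of the raw output should not be assumed;
* re-polishing a corrected matrix re-anchors on its own row medians,
  which differ from the saved ones by `2^(rowmed(C*))`; each naive
  re-run rescales rows by that same factor. `run_tampor` therefore
  accepts `row_medians=` so a result can be re-polished under its stored
  restoration constants, where it is an exact fixed point (stops at
  iteration 1).

## Defaults

| parameter | default | meaning |
|---|---|---|
| `mode` | `gis_plus_nonGIS` | denominator tuning (aliases `noGIS`, `GIS`, `useAllNonGIS`) |
| `tolerance` | 1e-8 | threshold on the Frobenius-norm difference (log2 units) |
| `max_iterations` | 250 | iteration cap |
| `max_missing_frac` | 0.5 | row removal at >= 50% missing |
| median convention | mean of central pair | even counts; present values only |

Summation order is fixed (row-major) so runs are bitwise reproducible.

## Synthetic data generator

`simulate_dataset` draws, in log2: feature base levels spanning
`dynamic_range_orders` decades (±2 SD; default 4), per-subject biological
deviations (`subject_sd`), group fold changes of magnitude
`spike_log2fc` on a `spike_fraction` subset, feature x batch effects
(`batch_effect_sd`), per-sample loadings (`loading_sd`) and technical
noise (`technical_noise_sd`). GIS columns carry the log2 of the
arithmetic mean of the case samples' latent abundances (a pooled
physical mixture), optionally distorted by a systematic prep offset
shared across batches (`gis_offset_sd`, emulating separately digested
pools), a per feature x batch defect (`gis_defect_sd`) and sparse gross
contamination of individual GIS channels (`gis_outlier_frac`, one-sided
high by `gis_outlier_log2_range` log2 units — low-side failures barely
move an abundance-space mean, high-side contamination corrupts it).
Missingness (random, whole feature x batch, or an optional left-tail
biased mode, off by default) is masked last; every component is stored
in the returned ground truth, which reconstructs the pre-mask matrix
exactly.

Two structural choices matter for interpretation. Groups are assigned
**balanced within batch** (the regime the method assumes; with
imbalanced batches the mixed batch medians absorb part of the group
effect). Spike signs **alternate up/down**: a one-directional spike set
shifts the affected group's sample medians (~0.08 log2 at 10% spiked),
which column centering then subtracts — attenuating every spiked fold
change and biasing null features. Sign-balanced effects, as in real
case-control proteomes, leave the sample medians neutral.

The fixed evaluation designs: `STANDARD_BENCHMARK` (1,000 features, 10
batches of 8 cases + 2 GIS, batch SD 1.0, loading SD 0.5, noise SD 0.3,
subject SD 0.15, 10% spikes at ±1 log2, seed 20230412);
`DEFECT_BENCHMARK` (plus GIS defect SD 0.5); `DIFFERENTIAL_BENCHMARK`
(5 batches → 20/group, subject SD 0); `REPLICATE_BENCHMARK` (400
features, 12 batches of 5 cases + 3 GIS, 30 subjects each replicated in
two batches, GIS prep offset SD 0.2, 2% GIS contamination at +6..12
log2). Problem sizes are desk-scale twins of the motivating cohorts,
chosen so the full battery runs in seconds while keeping ≥ 20 samples
per group and ≥ 10 batches where the claims need them. RNG is NumPy's
PCG64 (`default_rng`); a design's seed fully determines its dataset.

What the generator does **not** emulate: peptide-to-protein rollup,
isotopic interference, instrument drift within a batch, missing-not-at-
random intensity floors (beyond the optional left-tail mode), and
correlated feature blocks (co-expression modules). Passing benchmarks
therefore demonstrate correctness of the algorithm under its own model,
not performance on any particular real cohort.

## QC metrics

Mean-SD series use the sample SD (n−1). Classical (Torgerson) MDS is
computed on Euclidean inter-sample distances over pairwise-complete
features, each squared distance rescaled by total/shared feature counts;
eigen-modes below 1e-12 of the leading eigenvalue are treated as noise.
Variance explained is a deliberately simple marginal decomposition: a
one-way method-of-moments between/within fraction per categorical
factor (truncated at 0), the squared Pearson correlation for continuous
traits — an approximation of mixed-model variance partitioning, not a
reimplementation. Differential abundance uses Welch's t-test (the
unequal-variance choice is conservative and costs little power here)
with Benjamini-Hochberg adjustment across testable features; features
with under two present values per group or zero variance in both groups
are flagged untestable. Note that testing on median-equalized data is
slightly miscalibrated in principle (the correction removes batch-shared
noise); with sign-balanced effects the null p-values remain KS-uniform
at the benchmark scale.

bicor follows the standard biweight midcorrelation: deviations from the
median weighted by `(1 - u^2)^2` for `|u| < 1`, `u = (x - median) /
(9 MAD)` with the raw (unscaled) MAD; zero-MAD vectors are undefined.
Replicate-pair and all-pair correlation shifts are computed on the
**ratio scale** (naive ratio output; polished matrix divided by its
restored row medians). On that scale a systematic GIS-vs-sample offset
is a component common to every sample's profile, which is what makes
mean inter-sample correlations positive; row-centering across samples
would force the mean pairwise correlation to ~0 and is deliberately not
applied. The one-tailed Welch t-test compares the absolute correlation
gains of improved pairs against the losses of worsened pairs.

## Known limitations

* Batches must be trait-balanced in `noGIS` mode; confounded designs
  cannot be rescued (use `gis_only` with sound standards instead).
* The norm-difference convergence statistic can, in principle, trigger
  on a norm-preserving cycle; the `delta_norm` variant and the trace are
  provided for diagnosis.
* The variance-explained estimator is marginal: correlated factors both
  claim shared variance, and fractions are rescaled if their sum exceeds
  one.
* The transposed multi-platform mode requires complete data and exactly
  one assay per shared accession per platform; monotone but strongly
  nonlinear platform responses are only partially linearized by the
  log-scale polish.
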