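# Methods

This note documents the statistical models behind `atacprog`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter when comparing
output across implementations.

## Coordinates and the atlas heuristic

All intervals are BED-style 0-based half-open. The atlas builder folds
patients in, in input order, resolving each incoming peak against the
current atlas peaks in coordinate order by repeated pairwise merges until no
overlap remains. The merge rule for an overlapping pair uses the overlap
fraction `f = |a∩b| / min(|a|, |b|)`:

- `f > threshold` (default 0.75, strict): the non-overlapping portions are
  removed, leaving the single intersection;
- `f ≤ threshold`: the overlapping portion is removed from both peaks and
  all nonempty remainders are kept as separate peaks.

The min-length denominator guarantees that full containment (`f = 1`)
always unifies, so no merge can produce an empty interval; Jaccard
(`|a∩b|/|a∪b|`) is available as an option but can leave two-sided
remainders. A fraction exactly equal to the threshold does **not** merge.
Every pairwise product strictly reduces total covered bases, so the
resolution loop terminates; the atlas is disjoint and sorted by
construction, rebuilding an atlas from itself is the identity, and the
per-patient atlas-size trajectory is non-decreasing. These invariants are
asserted and property-tested, and the builder is checked against a naive
re-application oracle on exhaustive small configurations.

Replicate reproducibility is a simple overlap filter — a peak of replicate
1 is kept when its best overlap fraction against replicate 2 reaches
`min_frac` (default 0.5, inclusive), reported on replicate-1 coordinates —
standing in for a full replicate-consistency (IDR) analysis, which is out
of scope. Cohort QC drops patients whose reproducible-peak count falls
strictly below the 25th percentile (linear interpolation). An optional
post-filter restricting the atlas to peaks supported by at least k patients
is off by default: the iterative heuristic itself imposes no such
constraint, so the filter is exposed separately rather than silently
applied. The saturation analysis permutes patient order (sampling without
replacement) `n_resamples` times (default 500) with a seeded generator and
reports mean and SD of the cumulative atlas size.

## Differential accessibility

Fragments are Tn5-corrected by shifting plus-strand intervals +4 bp and
minus-strand intervals −5 bp (whole-interval shift; lengths preserved) and
assigned to atlas peaks by fragment midpoint — the atlas is disjoint, so
assignment is unambiguous; a fragment whose midpoint falls outside every
peak is not counted.

Size factors are DESeq-style median-of-ratios over peaks with nonzero
counts in every sample, with a total-count fallback (warned) when no such
peak exists. Each peak is then fit by a negative-binomial GLM with log link
and offset `log(size factor)`:

```
log mu_s = offset_s + b0 + b1 * group_s + b2 * log(depth_s) + b3 * margin_s
```

with group coded 1 for recurrent, nuclear read depth entering on the log
scale (the functional form is a package choice) and margin status binary.
Dispersion is a per-peak method-of-moments estimate on normalized counts
using pooled within-group variance (`alpha = (v − mu)/mu²`, floored at
1e-8, the Poisson limit); full empirical-Bayes dispersion shrinkage is a
deliberate simplification left out. The Wald statistic for `b1` is referred
to a **t distribution with residual degrees of freedom** rather than the
normal: with 16 samples and 4 coefficients the normal reference is
anticonservative (measured type-I ≈ 0.074 at nominal 0.05 on null NB
cohorts, essentially `P(|t_12| > 1.96)`), while the t reference restores
≈ 0.05. `log2FC = b1/ln 2`. Non-converging peaks are flagged with NA
statistics, never dropped silently.

The signature keeps peaks with `|log2FC| > 1` and Benjamini–Hochberg
adjusted `p < 0.001`, both strict, with BH computed across all tested atlas
peaks (not only expressed or pre-filtered ones). Expression concordance
maps every tested peak to its nearest gene by TSS distance (ties to the
smaller coordinate) and compares signature-gene expression log fold changes
to unchanged-peak genes with a two-sided two-sample KS test.

## Motif scanning and ridge regression

The scanner computes, at every position on both strands, the log-odds score
`sum log2(p_ij / bg_j)` of the PWM against its background (pseudocount 1e-4
guards zero entries; ambiguous bases contribute 0, i.e. background). A peak
is a hit for a TF when any window reaches the threshold — by default 0.8 of
the motif's maximal attainable score, since an exact null-distribution
p-value machinery is out of scope. Sequences shorter than the motif score 0.

The ridge problem `argmin ||y − Xβ||² + λ||β||²` is solved in closed form on
standardized columns with an unpenalized intercept (fit on centered data);
coefficients are reported back on the original binary scale. Standardizing
before penalization follows common practice for penalized regression on
binary designs; the choice is documented because it changes the effective
penalty per column. Zero-variance columns are retained with a warning. The
λ grid is 50 log-spaced values over `[1e-4, 1e4] · (||X'y||/n)`; 5-fold CV
with seeded, shuffled folds picks the minimum-mean-squared-error λ (no
1-SE rule). The solution is verified against the normal equations to 1e-8
and against an independent numerical minimizer of the objective; with the
seed fixed the chosen λ is deterministic, and across seeds it moves by at
most one grid step when the CV curve has a well-determined minimum.

## ATAC-array scoring

Per-probe normalization is the linear ratio cy5/cy3 (reference gDNA
controls per-probe hybridization efficiency); log2 is available as an
option. Linear is the default because it makes the cohort Prognosis-Score
scale (medians around 0.6) natural; whether class medians should be taken
on the linear or log scale is genuinely underdetermined, so both are
supported. Class medians use the standard even-count convention (mean of
the central pair). The scores are

```
blue_score = BLUE / (CTRL − CGH)
red_score  = RED  / (CTRL − CGH)
diff_score = (BLUE − RED) / (CTRL − CGH)
```

computed per array (controls are not pooled across the cohort); an array
with `CTRL ≤ CGH` has failed its positive control and is rejected. Scores
are exactly invariant to rescaling all intensities. The median split
assigns above-median scores to the good-prognosis group; a score exactly at
the median is called good and flagged as a tie (deterministic and
auditable), and an all-identical score vector is flagged indeterminate.
The per-sample RED/BLUE call is a Welch t-test on log2 ratios with a
median-comparison shortcut when both classes are constant. Array–sequencing
concordance is Spearman rank correlation (mid-rank ties) with a Fisher-z
confidence interval.

## Survival analysis

Kaplan–Meier estimation uses the product-limit estimator (events before
censorings at tied times); the median is the earliest time with
`S(t) ≤ 0.5`, undefined if never reached. The weighted log-rank family is
computed from the pooled event table: at each event time the group-wise
observed deaths are compared to expectation under the multivariate
hypergeometric law, with covariance
`Cov(d_g, d_h) = d(n−d)/(n−1) · (p_g δ_gh − p_g p_h)`. Unit weights give
the Mantel–Cox test, at-risk weights the Gehan–Breslow–Wilcoxon variant,
and ordered scores 1..k on unit weights the 1-df test for trend. The O−E
vector sums to zero by construction and is asserted on every run; the
statistic is invariant to monotone time transforms.

The two-group hazard ratio defaults to a Cox partial-likelihood fit
(Newton–Raphson, via lifelines). The O/E (Pike) estimator
`(O1/E1)/(O2/E2)` with `SE(log HR) = sqrt(1/E1 + 1/E2)` is kept as
`method='pike'` for comparability with test-based reporting, but it is
materially pulled toward 1 when the true hazard ratio is far from 1
(measured: true HR 3 at 200 per group gives Pike ≈ 2.56 on average vs Cox
≈ 3.06), so it is not the default. The reference group of every ratio is
stated in the output rather than implied.

The median-split stratification joins scores to survival records, splits at
the cohort median, and reports per-group KM medians, Mantel–Cox and
Gehan–Breslow–Wilcoxon tests and the hazard ratio of poor vs good; groups
of fewer than two patients refuse testing with a warning. The four-group
stratification crosses the score call with binary HNF1b nuclear status in
the order good+positive, good+negative, poor+positive, poor+negative,
reports group fractions and medians, and runs the trend test; patients
missing either marker are excluded and listed.

## Synthetic cohorts: what they emulate

The generator reproduces the statistical structure the pipeline assumes,
with all draws derived from one seed (fixed seed ⇒ byte-identical output):

- **Cohort**: `round(n·frac_recurrent)` recurrent patients (defaults 16 and
  0.375 → 6 + 10, a discovery-scale cohort); exponential DFS with the
  non-recurrent median at 845 days and the recurrent hazard scaled by
  `hazard_ratio_groups` (default 3, in line with a cohort whose median DFS
  differs ~3-fold); censoring Bernoulli(0.2) with censoring time uniform
  before the event. Exponential survival keeps log-rank and hazard-ratio
  expectations in closed form.
- **Peak calls**: a disjoint template of `n_atlas_peaks` 500-bp peaks on a
  single synthetic chromosome `chrS`; each patient carries a
  Bernoulli(0.9) subset, present in both replicates with Gaussian boundary
  jitter (SD 10 bp) plus ~10% replicate-private noise peaks in the gaps.
- **Counts**: NB with `Var = mu + alpha·mu²` (default `alpha` 0.05,
  `base_mean` 100 fragments/peak — typical deep-coverage ATAC peaks);
  planted peaks carry log2FC ±2 in the recurrent group; lognormal
  library-size factors; nuclear read depth (lognormal) and margin status
  (Bernoulli 0.3) injected into the mean so covariate adjustment is
  exercised.
- **Motifs**: Bernoulli(0.1) background hits over 20 TFs; each planted TF's
  hit probability is raised by `0.4·|effect|` in the differential peaks
  whose direction matches the effect sign, so the ridge coefficients
  recover the planted signs.
- **Array scans**: per-probe log2 Cy5/Cy3 ratios Normal(log2 class median,
  0.1), so the linear class median equals its configured target. Defaults
  put the good-prognosis blue score at 0.72 and the poor at 0.48
  (cohort median 0.6, matching the scale of a real score distribution);
  raw hybridization intensities are log-normal, an assumption, since their
  true distribution is not characterized.
- **Expression**: one gene per template peak with log2 fold changes shifted
  −1 for genes nearest differentially *closed* peaks and unshifted near
  opened peaks, mirroring the empirically asymmetric concordance.

What it does **not** emulate: real genomic sequence (motif plantings are at
the hit-matrix level except where the scanner is tested on constructed
sequences), mappability and GC structure, correlated peaks, mitochondrial
contamination, batch or dye-bias effects on the array, and non-proportional
hazards. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to these real-data
artifacts.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale as a package
choice: atlases of 400–2000 peaks, cohorts of 16–40 patients, 3–20
simulation replicates per stochastic property. Measured operating
characteristics at these scales: differential-caller type-I ≈ 0.05 at
nominal 0.05 on null cohorts and ≥ 0.90 recovery of planted |log2FC| = 2
peaks at 8 vs 8 patients; ridge sign recovery of ±0.5 planted effects
≈ 1.0 over 2000-peak replicates; blue-score mean absolute bias < 0.01 at
noise SD 0.1 with 500 probes per class; and the 40-patient median-split
log-rank separates at p < 0.05 in ≈ 95% of replicate cohorts at true
hazard ratio 3.

Degenerate inputs are handled explicitly rather than silently: empty
replicate sets filter to empty; malformed intervals, unknown probe classes,
missing classes, nonpositive survival times, empty survival groups and
unmatched patient ids raise; nonpositive Cy3 probes are dropped with a
count; tie rules (merge threshold equality, median-score ties, equidistant
TSSs) are all deterministic and stated above.
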