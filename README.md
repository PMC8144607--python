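# atacprog

Chromatin-accessibility prognostics for resected tumor cohorts: from
per-patient ATAC-seq peak calls to a cross-patient peak atlas, a
differential-accessibility signature, transcription-factor motif effects,
ATAC-array Prognosis Scores, and Kaplan–Meier survival stratification.

The package is aimed at computational biologists who want to run, test or
extend this analysis chain on their own cohorts — or on fully synthetic
cohorts with known ground truth, which the built-in generator produces so
that every stage is verifiable without access to controlled patient data.

## What it computes

1. **Peak atlas** (`atacprog.atlas`). Replicate peak calls are filtered by an
   overlap-fraction reproducibility rule, then folded patient by patient into
   a disjoint atlas: two overlapping peaks with overlap fraction
   `f = |a∩b| / min(|a|,|b|) > 0.75` are unified to their intersection,
   otherwise the overlapping portion is removed from both. Includes
   bottom-quartile cohort QC and a resampled saturation curve.
2. **Differential accessibility** (`atacprog.differential`). Fragments are
   counted into atlas peaks by midpoint, normalized by median-of-ratios size
   factors, and tested per peak with a negative-binomial GLM
   (`log μ = offset + β₀ + β₁·group + covariates`), controlling for nuclear
   read depth and margin status. The signature is called at
   `|log₂FC| > 1` and BH-adjusted `p < 0.001`, and concordance with
   expression changes is assessed by two-sample Kolmogorov–Smirnov tests on
   nearest-gene log fold changes.
3. **Motif ridge regression** (`atacprog.motifs`). Peak sequences are scanned
   on both strands with PWM log-odds scores into a binary peak × TF matrix
   `X`; with `y` the per-peak log₂ fold change, the TF effects solve
   `β̂ = argmin_β ‖y − Xβ‖² + λ‖β‖²`, with λ chosen by seeded 5-fold
   cross-validation. Positive coefficients mark motifs enriched where
   chromatin opens in recurrent tumors.
4. **ATAC-array scoring** (`atacprog.array`). Two-channel scans (sample ATAC
   library in Cy5 vs reference gDNA in Cy3) are normalized per probe as
   cy5/cy3; probe classes RED/BLUE/GREEN/BLACK are summarized by medians and
   the Prognosis Score is `BLUE / (CTRL − CGH)`. Above-median scores carry
   the good-prognosis signature; a Welch t-test on RED vs BLUE log-ratios
   gives the per-sample call.
5. **Survival stratification** (`atacprog.survival`). Kaplan–Meier curves,
   the weighted log-rank family (Mantel–Cox, Gehan–Breslow–Wilcoxon, test
   for trend), Cox/Pike hazard ratios, the median-split stratification and
   the four-group score × HNF1b-nuclear-localization stratification.
6. **Synthetic cohorts** (`atacprog.simulate`). Seeded generators for all of
   the above with planted ground truth.

## Worked example

```python
from atacprog import (SimulationConfig, simulate_cohort, simulate_peak_sets,
                      reproducible_peaks, build_atlas,
                      simulate_counts_and_motifs, fit_nb_glm,
                      call_differential)

cfg = SimulationConfig(seed=1)          # 16 patients: 6 recurrent, 10 not
truth = simulate_cohort(cfg)
sets = simulate_peak_sets(truth, cfg)
rep = [reproducible_peaks(r1, r2) for r1, r2 in sets.values()]
atlas = build_atlas(rep)
counts, meta, motifs, planted = simulate_counts_and_motifs(truth, atlas, cfg)
res = fit_nb_glm(counts, meta)
sig = call_differential(res, lfc_threshold=1, fdr=0.001)
print(len(atlas), len(sig), len(sig.open_in_recurrent))
```

prints

```
1099 113 46
```

an atlas of 1099 disjoint peaks built from the 16 patients' replicate calls
and a 113-peak differential signature at the thresholds above, of which 46
peaks open in the recurrent group. The generator planted 125 differential
peaks (50 open in recurrent + 75 in non-recurrent); the caller recovered
113 of them with no false calls at this cohort size (6 vs 10 patients).

The same chain is exposed as a CLI:

```bash
atacprog simulate --seed 1 --outdir cohort/
atacprog atlas build cohort/PT*_rep1.bed --out atlas.bed
atacprog array-score --probes cohort/probes.tsv \
    --scan PT001 cohort/PT001_scan.tsv ... --out scores.tsv
atacprog survival-stratify --scores scores.tsv \
    --clinical cohort/clinical.tsv --out strat.json
```

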