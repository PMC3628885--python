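# chronoclass

Statistical pipeline for developmental expression profiling of miRNAs (and
other small RNAs) across broad age categories — fetal, early-postnatal
("young") and adult brain tissue — from two-colour spotted-array data and
pooled TaqMan qPCR panels.

The package is aimed at analysts working with dual-channel microarray
exports (GenePix/Acuity-style per-feature tables) and SDS-style Ct exports
who want the full chain — scan merging, QC filtering, normalization,
model-class assignment, FDR calibration, enrichment, clustering and
2^−ΔΔCt screening — as tested, seedable library code rather than a one-off
script. Every stage is exercisable on synthetic data with known planted
ground truth, so the pipeline's operating characteristics (false-discovery
control, pattern recovery, null calibration) are themselves tested.

## The model

Each gene g has one mean expression level per age category: μ_F, μ_Y, μ_A
(log2 sample/reference-pool ratios), with Gaussian noise around the
category mean. Two questions are asked per gene:

* **Is anything changing?** The classical one-way omnibus F test of
  {μ_F, μ_Y, μ_A} against a single common mean. Significance is decided at
  a p-value threshold calibrated by simulation in the style of SAM:
  age-category labels are permuted whole-column (preserving gene–gene
  correlation), all omnibus p-values recomputed, and

      FDR(t) = median over permutations of #{null p ≤ t} / #{observed p ≤ t},

  monotonized in t; the chosen threshold is the largest t with
  FDR(t) ≤ 1%.

* **What is changing?** Backward model selection over the category means:
  starting from three free means, partial F tests evaluate each merge of
  adjacent (in estimated-mean order) groups; the merge with the largest
  p-value is applied while that p exceeds the working α (the calibrated
  threshold), leaving one of the 5 equality partitions. Ordering the
  surviving group means gives the gene's **model class** — one of the 13
  weak orderings of three labelled means, e.g. `F<Y=A` (class 1, fetal
  low), `F=A<Y` (class 5, postnatal spike), `F<Y<A` (class 7, monotone
  rise), `F=Y=A` (no change).

Around this core: robust (least-absolute-deviations) calibration merges
10%- and 100%-laser-power scans to extend dynamic range past the 16-bit
ceiling; four feature filters (pixel fraction above background, spot R²,
dual-channel saturation, visual flags) plus per-array LOWESS normalization
of M on A produce the gene × sample matrix; permutation tests assess
enrichment of annotations (e.g. vendor-predicted "novel" sequences) within
a model class; hierarchical clustering with a 1 − Pearson-r metric orders
genes and samples; and the TaqMan module implements 2^−ΔΔCt relative
quantification against the geometric mean of RNU44/RNU48/U6, with a
Ct > 29 robust-expression filter, guide-strand selection and a pooled 2-SD
fold-change spike screen.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (1083 features × 47 arrays, 36/9/2 fetal/young/adult, 10% of features
carrying a planted directional pattern at 6 noise-SDs):

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_merge_scans.py
python analysis/03_filter_normalize.py
python analysis/04_calibrate_fdr.py --seed 0 --nsims 2500
python analysis/05_classify.py --seed 0
python analysis/06_enrichment.py --seed 0
python analysis/07_cluster.py
python analysis/08_taqman.py
```

which prints, for seed 0:

```
merged 47 arrays; green-channel gain 9.92-10.05 (median 9.99)
1083 features in; 1027 genes retained across 47 arrays (presence >= 70% ...)
2500 simulated datasets: a p-value of 6.02881e-06 controls the FDR at 1%
  (estimated 0.0000); 103 of 1027 genes significant
pattern recovery on planted non-null genes: 100.0%
fetal covariate scan (gestational_weeks): 2 genes significant at 1% calibrated FDR
class F<Y=A: 4 novel genes observed (null mean 0.00); permutation p = 0.0010
sample leaf order groups the age categories into 3 runs (3 = perfectly contiguous)
2-SD screen flags 6 assays; 6/6 planted spikes recovered
```

Reading this: the scan-merge recovered the planted 10× gain; the presence
rule removed the chronically weak features; the calibrated threshold
admitted 103 genes (the planted non-null features that survived QC) with
no estimated false discoveries; every recovered gene was assigned its true
model class; the within-fetal gestational-age scan found essentially
nothing (nothing was planted); novel-feature enrichment in class 1 was
detected by age-label permutation; samples clustered contiguously by age
category; and the qPCR screen flagged exactly the planted single-timepoint
expression spikes.

The same pipeline runs as one call — `chronoclass.run_pipeline(config,
out_dir)` — writing every stage output and a machine-readable manifest;
byte-identical under a fixed seed.

## Layout

    src/chronoclass/   library: synthetic, scan_merge, qc, anova, fdr,
                       enrich, cluster, taqman, io, pipeline, validation
    analysis/          numbered narrative drivers (see worked example)
    scripts/           acceptance.py (reproducibility entry point)
    tests/             pytest suite, incl. operating-characteristic checks
    docs/methods.md    modelling assumptions, parameter choices, limitations
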