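# Methods

This note records the statistical model, the choices made where the design
was genuinely open, the numerical conventions, and what the synthetic-data
studies do and do not demonstrate.

## Per-gene model and the two p-values

Expression enters the model as normalized log2(sample/reference-pool)
ratios. For gene g and sample s in age category c(s) ∈ {F, Y, A}:

    x_gs = μ_g,c(s) + ε_gs,   ε_gs ~ N(0, σ_g²) i.i.d.

Groups are unbalanced (the default design is 36 fetal / 9 young / 2 adult);
all F statistics use unweighted cell means with the usual residual-variance
denominator, and missing entries (features filtered on some arrays) simply
reduce the per-group counts.

Two distinct quantities are computed per gene, and keeping them distinct is
a deliberate design decision:

1. **Significance p-value** — the classical omnibus one-way ANOVA F test of
   the 3-mean model against a common mean (df = k−1, N−k over the observed
   categories). Under the Gaussian null this p is exactly uniform, which is
   a prerequisite for the permutation-based FDR calibration and for the
   uniformity checks in the test suite.
2. **Model class** — backward selection at the working level α: among the
   two merges of adjacent groups in estimated-mean order, the one with the
   largest partial-F p-value is applied if that p > α; repeated until no
   merge is acceptable or all means are merged. Only adjacent merges are
   considered because a merge of non-adjacent means cannot produce a weak
   ordering. Ordering the surviving group means yields one of the 13 weak
   orderings of {F, Y, A}; exact ties are resolved conservatively toward
   equality.

A plausible alternative — using a p-value derived from the selection path
itself (the smallest partial-F p along the greedy path, which is the
smallest α at which the gene retains structure) — was evaluated and
rejected as the significance measure: its null distribution is markedly
non-uniform (the tail probability at p ≈ 0.002 is inflated roughly
three-fold), which would silently mis-calibrate any downstream FDR
machinery. It is still reported as `path_p` for diagnostic use.

The two views can disagree on boundary genes (a gene may pass the omnibus
threshold yet merge fully under selection, or vice versa); such genes are
rare at small α and are reported with their selected class as-is.

### Selection consistency

Backward selection is a greedy sequential procedure; the exhaustive
alternative (fit all five equality partitions, keep the most parsimonious
one whose expansion to three free means is unsupported at α) is implemented
in the test suite as an independent oracle. The two provably differ on
boundary instances — the oracle judges adequacy with a single 2-df test
where the sequence uses two 1-df tests — and on diffuse random instances
(group means ~ N(0,1), noise 1, α = 0.05) they disagree on about 11% of
draws, always in the direction of the sequential procedure retaining a
2-group split the 2-df test would not support. Agreement is therefore
measured where the question is well-posed: instances that are either null
or carry a planted pattern at 6 noise-SDs, at the calibrated α. There the
two procedures agree on ≥ 99% of 10,000 instances, which is what the
acceptance check asserts.

## FDR calibration

Null p-value pools are built by whole-column permutation of the age labels
(2500 permutations by default; studies in the tests use 200–500 for speed),
preserving the gene–gene correlation structure; a parametric alternative is
deliberately not the default. For candidate thresholds t (the sorted
observed p-values):

    est(t) = median over permutations of #{null p ≤ t} / max(1, #{obs p ≤ t})

The median (rather than mean) summary is robust to occasional permutations
that concentrate signal; the mean is available via `summary="mean"`.
Monotonicity in t is enforced by the standard q-value-style adjustment,
est(t) ← min over t′ ≥ t of est(t′). A left-to-right running maximum is
equally monotone but lets the noisiest estimates — at the smallest
thresholds, where the denominator is 1 or 2 — dominate the entire curve,
and fails the degenerate sanity case (target 1 must discover everything).
The chosen threshold is the largest t with est(t) ≤ target; if none
qualifies, the smallest observed p is reported with zero discoveries.

Measured operating characteristic (recomputed by `scripts/acceptance.py`):
on 50 replicates of 2000 features × 12/12/12 with 10% non-null at 6
noise-SD separation and 300 permutations each, the mean realized
false-discovery proportion at the nominal 1% target is ≈ 1.1–1.3%
(slightly above nominal because the permutation null also absorbs the
planted-signal genes' inflated within-group variance, and the median of
small integer counts is coarse; the deviation is well inside the
Monte-Carlo band).

The within-period covariate scans (expression on gestational weeks within
fetal samples; on postnatal days within young) use per-gene simple linear
regression slope tests and the same calibration machinery with the
covariate permuted instead of the labels.

## Enrichment testing

The statistic is the count of annotation-positive ("novel") genes assigned
to the target class — the count rather than the fraction, because at fixed
class occupancy the count is monotone in the fraction and does not
degenerate when the class empties. The null permutes *age-category labels*
and re-runs the entire classification (vectorized, so 999 permutations of a
~500-gene matrix take seconds). P-values use the add-one convention
p = (1 + #{null ≥ obs}) / (1 + n_perm), which can never return 0.

A property worth stating plainly: label permutation destroys the expression
structure itself, so for any dataset with real structure and any occupied
class the null counts collapse toward zero and the test reports
significance — it is a test of "this class is occupied beyond
label-permutation chance, with novel members", not of annotation
composition conditional on occupancy. Exact uniformity of the p-value
therefore holds on the exchangeable null (no age structure, annotation
independent), and that is what the calibration test verifies — using the
optional randomized tie-break, since the conservative add-one p of a
discrete statistic is by construction super-uniform. A cheap cross-check
that *conditions* on occupancy (permuting the annotation labels instead) is
provided as `annotation_permutation_null`.

## Scan merging

The two scans are modelled as linearly related — high ≈ gain · low — with
clipping at the 16-bit ceiling (65535) and multiplicative noise. The
calibration is a least-absolute-deviations line (statsmodels QuantReg at
q = 0.5) of high on low background-subtracted intensity
(median_fg − median_bg, floored at 1 so downstream logs stay finite), over
features unsaturated in both scans and above background in both; at least
10 support features are required and a non-positive slope is rejected as a
symptom of swapped inputs. Features with ≥ 20% saturated pixels in the
high scan — the same constant as the published saturation filter — take
slope · low + intercept instead of their clipped value. QC fields are
merged per-field from the more reliable scan: pixel fraction and R² as the
better of the two (a spot resolved in either scan is usable), saturation
fraction, flag and background from the scan actually used.

Whether the original merging operated on intensities or on ratios is not
determinable from the available description; intensities per channel were
chosen and the scheme is isolated behind this module's interface.

## QC filters, normalization, assembly

The four filters are: pixel fraction above background + 2 SD ≥ 0.70 in
either channel; spot-regression R² > 0.5 (strict); not (≥ 20% saturated in
both channels); no visual flag. Pixel statistics are consumed from the
precomputed `frac_pixels_gt_bg2sd` column — image-level recomputation is
out of scope. The filters are order-independent and idempotent.

LOWESS normalization of M on A uses span 0.4, tricube weights, 3 robustness
iterations (common MA-plot defaults; the span is exposed). The fit is
linear in M, so the output is exactly invariant to a constant M offset.
At least 30 surviving features per array are required.

How a cross-array gene set is consolidated from per-array filters is not
specified anywhere authoritative; the rule adopted is a presence threshold:
a gene is kept if it passed QC on ≥ 70% of arrays (the constant mirrors the
pixel filter; configurable), with remaining holes left as NaN and tolerated
by the per-gene fits. The retained-gene count under planted per-array
failure rates matches the closed-form binomial expectation in the tests.

## Clustering

Distance is 1 − Pearson r between gene rows over pairwise-complete samples
(Spearman available), range [0, 2]; rows with zero variance are rejected,
and pairs sharing < 3 samples get the maximal distance 2 with a warning.
Linkage is average by default (complete available) — the original metric's
linkage is unstated. Leaf order comes from scipy's deterministic
agglomeration (earliest eligible pair first, so lower original indices
merge first on ties); dendrograms serialize to Newick via scikit-bio.

## TaqMan 2^−ΔΔCt

Geometric-mean normalization over RNU44, RNU48 and U6 is implemented as the
arithmetic mean on the Ct scale — exactly equivalent on the linear 2^−Ct
scale. ΔCt = Ct − normalizer; ΔΔCt is taken against a named reference
timepoint; fold = 2^−ΔΔCt, reported on both scales, identically 1 at the
reference. The robust-expression filter drops assays with raw Ct > 29 at
every timepoint, and passenger-strand assays are excluded throughout.

The 2-SD spike screen pools all log2 fold changes across retained assays
and non-reference timepoints and flags |value − mean| > k·SD (k = 2). The
log2 scale (symmetric in up/down) and the pooled SD are choices — the
original description fixes neither scale nor pooling; a linear-scale option
exists. Censored reactions (Ct = 40, the SDS "undetermined" export
convention) propagate as flagged detection-limit bounds, never as point
values: with single-run pools there is no replicate variance to absorb
them. Epoch-pair fold-difference tabulations (bins 2/5/10/100) average
log2 relative quantities within each epoch before differencing. Q–Q data
use Blom plotting positions against the standard normal.

## Synthetic data

The generator emulates the study design: one array per donor sample, each
sample channel competing against a common reference pool mixed from all
samples; per-feature reference brightness uniform on log2 [8, 13]; planted
category means follow one of the 13 weak orderings with adjacent-group
separation `effect_size` (log2 units) and i.i.d. Gaussian noise
(`noise_sd`, default 0.25); an intensity-dependent dye bias
(0.3 − 0.05·(A − Ā)) is injected for LOWESS to remove; the 100% scan is
gain 10 × the 10% scan with 3% multiplicative noise, clipped at 65535.
QC failures are a property of the printed spot: per filter, a configurable
fraction of features is chronically weak (failing on ~85% of arrays, so the
presence rule removes them) while sound features fail at 0.5%; both scans
of an array share one QC realization. Default composition mirrors the
emulated platform: 1083 features, 373 of them "novel", 36/9/2 samples, 90%
null / 10% directional class mix at 6 noise-SDs of separation. TaqMan pools
get near-constant reference Cts (20/22/24), target Ct = baseline −
log2(relative abundance) + noise, censoring at 40, a configurable fraction
of never-robust assays (baseline Ct 31–36) and of single-timepoint spikes
(+6 log2 by default).

What the generator does **not** emulate — and hence what passing tests do
not establish for real data: heteroscedastic or heavy-tailed noise,
correlated genes (each feature's noise is independent), dye-swap effects,
spatial artefacts, partial degradation or post-mortem-interval effects,
probe cross-hybridization, and amplification-efficiency differences between
qPCR assays. The diagnostics module (pooled residual Q–Q slope, per-category
variance ratios, excess kurtosis) reports departures but gates nothing.

## Problem sizes and determinism

Simulation studies run at sizes chosen to keep the full suite comfortable
on a laptop-class single core: calibration studies at 2000 genes × 36
samples with 200–500 permutations (2500 remains the library default for
real runs), the oracle comparison at 10,000 single-gene instances, the
uniformity checks at 10,000 pooled p-values. One config seed fans out into
per-stage child seeds through `numpy.random.SeedSequence`, so any stage can
be re-run alone with identical randomness; a full pipeline run is
byte-identical under a fixed seed, which the test suite asserts file by
file.

## Known limitations

* With only 2 adult samples (the default unbalanced design) the adult mean
  is poorly determined; classes separating the adult mean need the larger
  planted effects to be recovered reliably.
* The enrichment test's compound null (structure × annotation) is inherited
  from the published procedure; see above.
* Backward selection at very small α with tiny groups (n ≤ 2) can retain
  structure on exact-fit degeneracies; such genes carry an `exact_fit`
  flag.
* The scan-merge linear model ignores scanner nonlinearity below
  saturation; with a strongly nonlinear response the substituted values
  would be biased, though the monotonicity guarantees still hold.
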