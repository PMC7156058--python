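# Methods

`splicerail` implements a statistical framework for evaluating mRNA splicing
and polyadenylation biomarkers of myotonic dystrophy type 1 (DM1). DM1 is
caused by an expanded CTG repeat; the phenotype used throughout is the Modal
Allele Length (MAL) — the mode of the repeat length measured in blood, in
repeat units. The framework asks how well probe-level exon-array expression
predicts MAL, how significant that prediction is against a simulated null,
and what statistical power a pre/post-treatment trial built on the predictor
would have.

## Predictor

Expression enters at the level of individual 25-mer probes (quantile
normalised, log2 transformed), never aggregated to probesets — this
sidesteps GC correction and probeset summarisation entirely. One evaluation
repetition:

1. randomly split participants into training (70%) and testing (30%);
   the training size is `floor(0.7 n)`, so 27 participants split 18/9;
2. within the configured candidate gene set, keep the (up to) 500 probes
   whose intensities have the largest |Pearson r| with MAL, computed on the
   training participants only;
3. fit a 2-component partial least squares regression (PLSR) of MAL on the
   selected probes; predict the held-out participants.

This is repeated (default 10,000 times; the test/validation profile uses
200) and all test-set predictions are pooled.

**PLSR algorithm.** Features and response are centred; unit-variance
scaling is off by default (configurable — with a correlation-based selection
step upstream, scaling changes little and unscaled NIPALS is the common
convention). For a univariate response the NIPALS inner loop collapses to a
closed form: the component weight is `w_a ∝ X_aᵀ y_a` exactly, so each
component costs a few matrix–vector products. This matters because the
resampled evaluation refits the model tens of thousands of times per
analysis. The implementation is verified in the test suite against
scikit-learn's independently written NIPALS (`PLSRegression(scale=False)`)
to 1e-8, and against ordinary least squares in the full-component limiting
case. If the residual covariance vanishes before the requested number of
components (rank-deficient training data), the fit stops early with a
logged warning.

**Comparators.** Lasso (penalty by internal cross-validation on the
training set), ordinary linear regression (minimum-norm least squares when
probes exceed participants) and a 500-tree random forest are available
behind the same interface, as checks that a signal is not an artifact of
the PLSR machinery. Their hyperparameters are deliberately plain defaults;
all are seeded.

**Selection details.** Pearson correlation is the default selection metric
(it matches the linear downstream model); Spearman is available. Probes
with zero training variance score r = 0. Ties in |r| break by probe index,
so runs are bit-reproducible. Repetitions whose training response is
constant are skipped and logged; more than 10% skips aborts the run.

## Evaluation statistics

* **R²** is the squared Pearson correlation of pooled predicted vs measured
  MAL. The `1 − SSE/SST` variance-explained variant is computed alongside
  (it can be negative and penalises calibration errors, not just rank
  disagreement); the correlation form is the headline number. Constant
  predictions define R² = 0.
* **RMSD** is the root mean squared pooled prediction error, in repeat
  units.
* **Pooling** concatenates every test prediction from every repetition
  (a participant contributes many predictions); a per-participant-averaged
  variant can be derived from the pooled records table.

**Simulated null and p-value.** The "random predictor" null is realised as
a phenotype permutation: each null replicate shuffles MAL across
participants and reruns the *entire* evaluation loop, probe selection
included, so the null inherits every opportunity for selection bias the
real pipeline has. The empirical p-value uses the add-one estimator
`p = (1 + #{null R² ≥ observed R²}) / (n_null + 1)`, which can never be 0.
The observed evaluation and the null replicates are independent runs (nulls
are not nested inside repetitions). Calibration is verified by simulation:
with no true signal, empirical p-values across replicate synthetic
experiments are uniform (Kolmogorov–Smirnov test).

## Power analysis

The clinical scenario: participants are biopsied pre- and post-treatment,
and a treatment with effect `e` reduces the *effective* repeat length (the
predictor's output) by the fraction `e` (defaults 0.10 / 0.20 / 0.50 for
small/medium/large effects). Per simulated cohort of size n (n = 10…200 in
steps of 10):

* true MAL values are resampled with replacement from the evaluation
  cohort's measured values;
* pre = MAL + ε₁ and post = (1 − e)·MAL + ε₂, with ε resampled with
  replacement from the evaluated model's pooled prediction errors
  (predicted − measured) — the analysis inherits the predictor's empirical
  error distribution rather than assuming one;
* the statistic is the mean per-participant difference pre − post (a mean
  percentage-change variant is available behind `statistic=`).

The reduction applies to the true MAL *before* the error is added, i.e.
treatment shifts the signal and leaves the prediction-error distribution
untouched; reducing the noisy prediction instead would shrink the error by
(1 − e) as a side effect, which has no biological justification.

The rejection region is fully simulation-based: the (α/2, 1 − α/2)
empirical quantiles of the statistic under the same construction with
e = 0 (two-tailed α = 0.05, 0.025 per tail). Power is the fraction of
treated cohorts falling outside it.

**Variance reduction on the grid.** Within one study size, the rejection
region is a property of the null alone, so it is estimated once — from 4 ×
n_sim null cohorts — and shared by all effects; the treated cohorts reuse
common random numbers across effects, which makes monotonicity in the
effect structural rather than statistical. The Monte-Carlo standard error
of a grid entry therefore has two terms: the binomial error of the treated
fraction and the propagated error of the estimated null quantiles
(`grid_entry_se` bounds the second term via the normal approximation
`f_alt · SE(q̂)` with the alternative density bounded by its mode). Tests
and the default n_sim (100,000 for production tables, 10,000 in the test
profile) are set against this combined error.

## Railway statistics

For exploratory, per-gene views, each probe's log2 intensity is regressed
on MAL by ordinary least squares; the two-sided p-value comes from the
slope's t statistic with n − 2 degrees of freedom. The railway plot shows
`sign(slope) · (−log10 p)` per probe, ordered by genomic position (1-based,
inclusive coordinates; ties break by probe id), coloured by probeset, with
symmetric thresholds at 0.05 and 0.05/n (n = probes in the plot), the
Bonferroni pair drawn saturated and the nominal pair faded.

Degenerate conventions (chosen here; standard formulas are silent):
constant intensities give slope 0 and p = 1 (score 0); an exact
non-constant linear fit gives p = 0 with the score capped at 300; constant
MAL is an error. The regression is written out via explicit normal
equations so these conventions are honoured exactly; `scipy.stats.linregress`
and a brute-force permutation test serve as cross-checks in the suite.

Fisher's method combines k independent p-values by referring
`−2 Σ ln pᵢ` to χ² with 2k degrees of freedom; a single p is returned
unchanged. Bonferroni correction is `min(1, m·p)`; with the HuEx chip's
1.4 million probesets as multiplicity and a combined probeset p of
4.19 × 10⁻¹⁰, the corrected value is 5.87 × 10⁻⁴.

## Synthetic data

The generator emulates the study conditions every statistical claim is
tested under:

* **Cohort**: 27 participants by default (a complete-tissue collection of a
  rare-disease study); MAL drawn log-uniformly over (100, 1300) repeat
  units, mimicking a right-skewed adult-onset cohort — real MAL
  distributions are not published in a fittable form, so log-uniform over
  the adult-onset range is a stated choice, not an inference. At most one
  participant can have MAL withheld (mimicking a measurement refusal);
  their expression is still driven by a hidden latent MAL.
* **Chip**: 50 genes × 2 probesets × 4 probes (400 probes) by default;
  probesets hold at most 4 probes (chip constraint). Probes get 25-mer
  sequences, strand, 1-based inclusive coordinates and chip (x, y); the
  annotation reports sequences 5′→3′ on the plus strand (reverse-complement
  of the designed probe for minus-strand genes).
* **Signal**: log2 intensity = baseline + β·z(MAL) + N(0, noise²), with
  β = ±effect_beta (one direction per probeset, emulating splice-in /
  splice-out events) at affected probes of biomarker genes (20% of genes;
  half the probes within them stay unaffected, so probesets mix signal and
  null probes), β = 0 elsewhere. The effect acts on cohort-standardised
  MAL so effect_beta is scale-free. Defaults effect_beta = 2,
  noise = 0.5, baseline N(7, 1) — log2 intensities in the realistic 4–10
  range with a clearly detectable but noisy signal.
* **Files**: raw intensities are written as 2^(log2 value) into per-sample
  CEL v4 binaries (pixel count 9 per cell, matching the scanner's 9-pixel
  summarisation), so quantile normalisation, the log2 transform and binary
  parsing are genuinely exercised end to end.

What the generator does **not** model: batch effects, ozone-type technical
drift, GC-content bias, probe cross-hybridisation, tissue differences, and
somatic mosaicism between blood and muscle. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
generative assumptions, not that any particular biomarker panel performs at
a given level on real cohorts.

## CEL v4 I/O

Only the version-4 binary layout is supported (little-endian; magic 64,
version 4, grid dimensions, length-prefixed header/algorithm/parameter
strings, cell margin, outlier/mask counts, then float32 mean / float32
stdev / int16 pixel triplets per cell). Text (version 3) files and Command
Console files (magic 59) are rejected with targeted messages; truncation
errors report the byte offset. Mask, outlier and sub-grid sections are
carried opaquely — the pipeline consumes mean intensities only. Round trips
are exact up to float32 storage precision, and the reader is cross-checked
against Biopython's independently maintained CEL parser. A plain-text
tabular matrix path (probe rows × participant columns) bypasses binary
files entirely.

## Preprocessing choices

* Quantile normalisation maps every participant onto the mean of the
  sorted columns; tied values within a column receive the mean of the
  reference quantiles they span (average-ties rule; unspecified in most
  descriptions of the method). It is idempotent and is applied to raw
  intensities *before* the log2 transform. Normalisation is computed per
  analysis batch (one tissue at a time) by construction, since the pipeline
  operates on whatever sample set it is given.
* Annotation filtering keeps probes on protein-coding transcripts of
  protein-coding genes covering CDS or UTR exons; probes with missing
  annotation are excluded and counted, never fatal; a retention report is
  emitted.
* Coordinates are 1-based and both-ends inclusive throughout.
* PCA outlier screening writes participant component scores only — no
  automatic exclusion, because outlier rejection in the original workflow
  is a visual judgement that cannot be automated faithfully.

## Problem sizes

The default test/validation profile uses 27 participants, 400 probes,
200 repetitions, 199 null replicates, 50 replicate experiments for the
calibration check, and 10,000 Monte-Carlo cohorts per power entry; these
sizes give Monte-Carlo errors comfortably below every asserted tolerance
while keeping a full validation run in minutes. Production-scale settings
(10,000 repetitions, 100,000 cohorts) are the configured defaults of
`PredictorConfig` and `PowerConfig`.

## Known limitations

* The correlation-based R² rewards monotone association, not calibration;
  consult `r2_variance_explained` and RMSD alongside it.
* The empirical p-value's resolution is 1/(n_null + 1).
* Power analysis assumes pre/post errors are independent draws from the
  cross-sectional residual pool; within-participant error correlation
  (which paired designs typically enjoy) would make these power figures
  conservative.
* `LassoCV` and random-forest comparators are orders of magnitude slower
  than the closed-form PLSR path; evaluation at production repetition
  counts is practical for PLSR and linear regression only.
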