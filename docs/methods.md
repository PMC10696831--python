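# Methods

`methnorm` studies a practical question in epigenomic biomarker work:
when a new cohort's methylation-array data are normalised on their own
rather than together with the reference panel an EpiScore was built
against, how much do individual-level scores move?  The package
provides the full loop — a synthetic two-cohort generator with known
truth, sixteen normalisation strategies, three quality metrics, an
elastic-net EpiScore, and the separate-versus-joint comparison — so
the question can be answered quantitatively and reproducibly.

## Array model

Infinium-style arrays report a methylated (M) and unmethylated (U)
fluorescence intensity per CpG probe.  Type I probes use two probe
sequences read in one colour channel (the probe's declared channel,
green or red); Type II probes use one sequence read in both channels
(green = M, red = U).  Methylation is summarised as

* beta value: `beta = M / (M + U + offset)` with `offset = 100`
  (conventional regularisation; betas live in [0, 1]),
* M-value: `log2((M + eps) / (U + eps))` with `eps = 1` (logit-like,
  preferred for modelling).

Pre-normalisation QC applies, once and in this order: a user-supplied
probe exclusion list (cross-hybridising/polymorphic probes), removal
of probes with detection p > 0.05 in more than 1% of samples, removal
of samples with detection p > 0.05 at more than 1% of probes, and
removal of probes with bead count < 3 in more than 5% of samples.
"More than" is strict: a probe failing in exactly 1% of samples stays.
Cohorts are combined on the intersection of their probe sets, probe
order following the first dataset.

## Synthetic data

The generator separates biology from technics.  Biology
(`simulate_true_betas`): plain probes draw a per-probe mean M-value
from a hypo/hyper bimodal mixture (60/40, centres ±2.5, sd 0.8) with
person-level noise (sd 0.5 on the M-value scale); imprinted-DMR probes
centre at beta 0.5 (sd 0.02); SNP-affected probes draw Hardy-Weinberg
genotypes (MAF 0.3) with beta centred at {0.05, 0.5, 0.95};
X-chromosome probes are hypermethylated in females by a margin of 0.3.
Two cohorts share all probe-level parameters (one probe-parameter RNG
stream) and differ only in the individuals drawn, so their biology is
exchangeable.

Technics (`render_intensities`): per probe and sample a total
intensity T ~ log-normal (mean 5,000, log-sd 0.3) splits into
`M = dye * (T*beta + background + noise)` and
`U = dye * (T*(1-beta) + background + noise)`, with additive
per-batch background (Type I 300, Type II 600 in batch 1; 450/900 in
batch 2), Gaussian intensity noise (sd 50), and multiplicative
per-channel dye gains (batch 2: green 1.3, red 0.9).  Type II probes
take the green gain on M and the red gain on U; both alleles of a
Type I probe share its declared channel's gain.  Out-of-band Type I
intensities are drawn from the background distribution alone.
Detection p-values are simulated directly (a 0.2% failure rate drawn
uniform above 0.05, the rest near zero) rather than derived from a
background model; bead counts are 3 + Poisson(14) with a 0.1%
low-bead rate.  This additive-background + multiplicative-dye model is
the simplest one under which the nomenclature distinctions between
the normalisation strategies (background yes/no, dye-bias correction
mode, between-array stratification) have observable consequences.

The phenotype is `log(BMI) = log 27 + 0.002*age - 0.03*male +
0.01*sum(PCs) + sum_j w_j * Mval_j + eps`, with weights
w ~ N(0, 0.075^2) on 50 randomly chosen plain CpGs and eps sd 0.08.
With 50 equal-scale causal effects each CpG carries about 2% of the
phenotypic variance regardless of the weight scale; 0.075 puts the
per-CpG signal in the regime a sparse regression can recover at
n = 500 while keeping a realistic residual share.  Default study size
is 5,000 probes (4,600 plain / 100 DMR / 100 SNP / 200 X, 72% Type II)
by 200 samples per cohort — a desk-scale stand-in for a genome-wide
array.

What the generator does *not* emulate: chip/position spatial effects,
copy-number artefacts, cross-hybridisation, probe-wise failure
correlation, cell-composition variation, and the long-tailed effect
sizes of real trait architectures.  Passing tests therefore show that
the pipeline's algebraic guarantees (invariances, orderings, metric
calibrations) hold and that the estimator works under a clean sparse
model; they do not certify performance on real arrays.

All randomness flows from `SeedSequence(seed).spawn`, one child stream
per stage (NumPy PCG64), so runs are bit-reproducible across platforms
and each stage is independently reproducible.

## Normalisation strategies

The registry pins sixteen strategies: `raw`, six named methods, and
nine combinatorial quantile-normalisation variants named by a
five-letter code — first letter `d`/`n` for background adjustment,
third letter `s`/`t`/`n` for between-array QN applied to Type I and II
probes separately / together / not at all, fifth letter likewise for
dye-bias correction (`nasen`, `dasen`, `naten`, `daten1`, `daten2`,
`nanet`, `danet`, `nanes`, `danes`).

Numerical choices, where the named method leaves them open:

* **Quantile normalisation**: classic rank/mean-order-statistic QN;
  ties map to the mean of the tied target values.  `daten1` normalises
  the M and U matrices separately, `daten2` pools them into one pass —
  the one pinned degree of freedom in the combinatorial family.
* **Background adjustment ('d')**: per sample and signal, Type I
  intensities are shifted additively so their 5th percentile matches
  Type II's, floored at 0.
* **Dye-bias correction**: per-sample cross-channel quantile
  equalisation — green and red values are mapped onto the average of
  the two channels' quantile functions, pooled over probe types
  (`t`) or within each type (`s`).  Because this uses only the
  sample's own values, `nanet`/`nanes` are strictly sample-wise here
  and show exactly zero separate-vs-joint difference; implementations
  whose dye step borrows across-sample information will show a small
  positive difference instead.  The robustness *ordering* (dye-
  correcting beats non-correcting under dye-dominated batch effects)
  is the portable conclusion.
* **SWAN**: per sample, equal numbers of Type I and II probes per
  CpG-count stratum form the subset; each type's intensities are
  interpolated onto the average of the two subset quantile
  distributions, values beyond the subset range shifted by the
  endpoint offset.  The "random" subset is seeded by
  `crc32(sample_id | stratum)` — stable across processes and cohort
  composition, which is what makes the sample-wise invariance exact.
* **BMIQ**: per sample and design type, a 3-state beta mixture is fit
  by EM (moment-based M-step, initial state means 0.1/0.5/0.9,
  log-likelihood tolerance 1e-5, max 500 iterations — dye-compressed
  Type II distributions can need ~220; betas clipped to
  [1e-6, 1-1e-6]).  Type II probes in the unmethylated/methylated
  states are quantile-mapped onto the corresponding Type I beta
  components; hemi-state probes are rescaled affinely between the
  transformed boundaries, preserving order and continuity.
* **PBC**: per sample, Gaussian-KDE (Silverman bandwidth, 512-point
  grid) peaks of negative and positive M-values per type; Type II
  M-values are scaled linearly per side so its peaks match Type I's.
* **Noob**: per sample and channel, background mean/sd from the
  out-of-band intensities read in that channel; in-band intensities
  replaced by the normal-exponential posterior-mean signal (strictly
  positive), then both channels scaled to their common mean level.
* **Funnorm**: control summaries (quantile sketch, mean, sd of each
  out-of-band matrix — stand-ins for hardware control probes),
  z-scored, SVD; each intensity quantile level is regressed on the
  first 2 components across samples and the fitted technical effect
  removed, per design type, with monotonicity enforced.
* **Tost**: Type II intensities quantile-mapped onto Type I "anchor"
  probes within CpG-count strata (empty strata fall back to all
  anchors); Type I probes QN'd across samples.

All methods guarantee betas in [0, 1] and sample-order equivariance.

## Quality metrics

* **DMRSE** = SD of imprinted-DMR betas / sqrt(n_samples); the default
  pools probes and samples into one SD (a per-probe-then-average mode
  is available via `mode="per_probe"`); expectation is anchored by the
  DMR probes' beta = 0.5.
* **GCOSE**: per SNP probe, 1-D 3-means (Lloyd's, centres initialised
  at 0.1/0.5/0.9) on betas across samples; mean squared error about
  each occupied centre, averaged over centres, then over probes.
  Probes with fewer than three distinct values are skipped.
* **Seabird**: each sample scored by mean beta over the
  sex-differentiated X probes; AUC for female (hypermethylated,
  positive class) vs male, ties counted half.  Orientation is fixed
  rather than folded to max(AUC, 1-AUC).  The metric table stores
  1 - AUC so lower is better for all three columns.

Methods are ranked per metric (average ranks on ties, missing values
ranked last) and ranks averaged into a mean overall rank.

## EpiScore

The target is the OLS residual of log(BMI) on age, sex and ancestry
principal components; the fitted covariate model is retained so scores
can be de-scaled back to kg/m² via `exp(score + covariate prediction)`
(an inversion of the residualisation; for small shifts the delta
method gives `d(kg/m²) ≈ BMI * d(score)`).  Features are CpG M-values,
optionally pruned to the top-k by standard deviation (ties broken by
probe id).  The elastic net uses mixing parameter alpha = 0.5 on a
100-point log-spaced penalty path spanning four orders of magnitude
below the analytic maximum, with the penalty chosen at the 10-fold
cross-validated MSE minimum (folds shuffled under the run seed).
Features are standardised internally and weights returned on the raw
M-value scale, so projection is `intercept + sum w_j * value_j`.
Model probes absent from a projection target are imputed at their
training mean (error above 20% missing).  Models declare their
training scale; projecting onto the other scale warns rather than
blocks, since both are used in practice.

## Separate-vs-joint robustness

For a target cohort, reference cohort and method: arm 1 normalises the
target alone, arm 2 normalises the harmonised combination and subsets
the target's samples afterwards; both arms run on the harmonised probe
intersection so any difference is attributable to normalisation alone.
Summary statistics per method: median absolute difference (MAD)
between arms, Pearson correlation with the phenotype per arm (both
arms are reported, since either could be the deployment arm) with
Fisher-z 95% intervals, incremental R² over an age+sex regression (in
percentage points), and percentile-place shifts
(`percentile = 100*(rank - 0.5)/n`, average ranks on ties) with the
between-arm Spearman correlation.  The benchmark loop is fail-soft: a
method that errors is recorded and skipped so one EM failure cannot
kill a 16-method sweep.

## Problem sizes and determinism

The shipped checks run the default 5,000 x 200+200 study for the
within-array invariance, 550-plain-probe pairs across ten seeds for
the dye-bias ordering, a 1,040 x 40+40 study for the 16-method
benchmark, and 2,000 probes x 500 samples per cohort for elastic-net
recovery — sizes chosen so the whole loop runs on a laptop-class
single core in a few minutes while leaving every qualitative
conclusion intact.  Repeated runs with the same seed produce
byte-identical outputs.

## Known limitations

* The technical model is additive background + multiplicative dye +
  Gaussian noise; real arrays add spatial and batch-chemistry effects
  no simulation parameter here captures.
* Funnorm's control summaries derive from out-of-band probes, not the
  physical control-probe set of any real array.
* The de-scaling transform is the exact inverse of the package's own
  residualisation, not a reimplementation of any published de-scaling
  procedure.
* GCOSE's and DMRSE's across-probe aggregation order is a documented
  choice (per-probe-then-average for GCOSE, pooled for DMRSE); other
  tools may aggregate differently and produce different absolute
  values while preserving method orderings.
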