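"""Synthetic two-cohort methylation-array data with ground truth.

The generator emulates the structure that the normalisation benchmark
relies on: two age-matched cohorts processed in different experimental
batches, Type I / Type II probe chemistries with different background
levels, per-channel dye bias that differs by batch, imprinted-DMR
probes centred at beta = 0.5, trimodal SNP-affected probes, sex-
differentiated X-chromosome probes, and a log(BMI) phenotype with
sparse CpG effects plus age/sex/ancestry covariates.

Biology and technics are separated: ``simulate_true_betas`` draws the
methylation state every probe *would* report on a perfect instrument,
and ``render_intensities`` pushes that truth through an explicit
technical model

    M = dye * (T * beta  + background + noise)
    U = dye * (T * (1 - beta) + background + noise)

with per-probe total intensity T ~ log-normal, additive per-batch
background (different for Type I and Type II probes) and multiplicative
per-batch, per-channel dye factors.  Type II probes read M in the green
channel and U in the red channel; both alleles of a Type I probe share
the probe's declared channel.  Type I out-of-band intensities are drawn
from the background distribution alone.

All randomness flows from ``numpy.random.default_rng`` seeded via
``SeedSequence(seed).spawn``, one child stream per stage, so any stage
is reproducible in isolation and the full study is reproducible end to
end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IntensityData, ProbeAnnotation, SampleSheet
from .errors import ValidationError


@dataclass(frozen=True)
class BatchParams:
    """Technical parameters of one processing batch.

    ``background_type1`` / ``background_type2``: additive background
    (intensity units) for Type I and Type II probes — Type I chemistry
    typically sits on a different background level than Type II.
    ``dye_grn`` / ``dye_red``: multiplicative channel gains; a
    green/red imbalance is the classic dye bias.
    """

    background_type1: float = 300.0
    background_type2: float = 600.0
    dye_grn: float = 1.0
    dye_red: float = 1.0

    def __post_init__(self):
        if self.dye_grn <= 0 or self.dye_red <= 0:
            raise ValidationError("dye multipliers must be positive")
        if self.background_type1 < 0 or self.background_type2 < 0:
            raise ValidationError("backgrounds must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for a synthetic cohort pair.

    Default sizes (5,000 probes x 200 samples per cohort) are a desk-
    scale stand-in for a genome-wide array; probe-class proportions and
    the Type II fraction (~0.72) mirror the production arrays.  The two
    default batches differ in background level and in green-channel
    gain, so between-array methods have real technical variation to
    remove while the biology of the cohorts is exchangeable.
    """

    n_plain: int = 4600
    n_dmr: int = 100
    n_snp: int = 100
    n_x: int = 200
    type2_fraction: float = 0.72
    n_samples: int = 200

    # technical model
    batch_a: BatchParams = field(default_factory=lambda: BatchParams(
        background_type1=300.0, background_type2=600.0,
        dye_grn=1.0, dye_red=1.0))
    batch_b: BatchParams = field(default_factory=lambda: BatchParams(
        background_type1=450.0, background_type2=900.0,
        dye_grn=1.3, dye_red=0.9))
    mean_total_intensity: float = 5000.0
    log_intensity_sd: float = 0.3
    noise_sd: float = 50.0

    # biology
    snp_maf: float = 0.3
    sex_ratio: float = 0.5           # fraction female
    dmr_noise_sd: float = 0.02       # probe-level spread around 0.5
    x_sex_margin: float = 0.30       # female minus male mean X beta
    person_mvalue_sd: float = 0.5    # person-to-person spread, M-value scale
    mean_age: float = 79.0
    age_sd: float = 0.6
    n_pcs: int = 10

    # phenotype
    n_causal: int = 50
    effect_sd: float = 0.075         # per-CpG weight scale on M-values
    pheno_noise_sd: float = 0.08     # residual sd of log(BMI)

    # assay nuisance
    detection_fail_rate: float = 0.002
    low_bead_rate: float = 0.001
    beadcount_mean: float = 14.0

    seed: int = 0

    def __post_init__(self):
        for f in ("n_plain", "n_dmr", "n_snp", "n_x", "n_samples"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{f} must be positive")
        if not 0.0 <= self.type2_fraction <= 1.0:
            raise ValidationError("type2_fraction must lie in [0, 1]")
        if not 0.0 < self.snp_maf <= 0.5:
            raise ValidationError("snp_maf must lie in (0, 0.5]")

    @property
    def n_probes(self) -> int:
        return self.n_plain + self.n_dmr + self.n_snp + self.n_x


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one cohort's rendered intensities."""

    true_beta: pd.DataFrame            # probe x sample
    genotypes: pd.DataFrame            # snp probe x sample, in {0,1,2}
    causal_cpg_ids: list[str] = field(default_factory=list)
    causal_weights: pd.Series | None = None
    true_signal: pd.Series | None = None   # methylation part of log(BMI)


@dataclass(frozen=True)
class SimulatedStudy:
    """A cohort pair rendered under different batch conditions, with
    shared biology (same manifest, same causal CpG weights)."""

    config: SimulationConfig
    manifest: ProbeAnnotation
    cohort_a: IntensityData
    cohort_b: IntensityData
    truth_a: TruthRecord
    truth_b: TruthRecord


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def simulate_manifest(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> ProbeAnnotation:
    """Build the probe annotation: class counts as configured, design
    type assigned by ``type2_fraction``, cpg_count drawn from {1, 2, 3}
    with probabilities (0.5, 0.3, 0.2)."""
    if rng is None:
        rng = _stage_rngs(config.seed, 6)[0]
    classes = (["plain"] * config.n_plain + ["dmr"] * config.n_dmr +
               ["snp"] * config.n_snp + ["chrX_sex"] * config.n_x)
    n = len(classes)
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    is_type2 = rng.random(n) < config.type2_fraction
    design = np.where(is_type2, "II", "I")
    channel = np.where(is_type2, "Both",
                       np.where(rng.random(n) < 0.5, "Grn", "Red"))
    chrom = np.where(np.array(classes) == "chrX_sex", "X",
                     rng.integers(1, 23, size=n).astype(str))
    cpg_count = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
    table = pd.DataFrame({
        "design_type": design, "channel": channel, "chromosome": chrom,
        "special_class": classes, "cpg_count": cpg_count,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return ProbeAnnotation(table)


def simulate_sample_sheet(config: SimulationConfig, cohort: str, batch: str,
                          rng: np.random.Generator,
                          prefix: str) -> SampleSheet:
    n = config.n_samples
    sample_ids = [f"{prefix}{i:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    age = rng.normal(config.mean_age, config.age_sd, size=n)
    pcs = rng.normal(0.0, 1.0, size=(n, config.n_pcs))
    table = pd.DataFrame({
        "cohort": cohort, "batch": batch, "age": age, "sex": sex,
    }, index=pd.Index(sample_ids, name="sample_id"))
    for k in range(config.n_pcs):
        table[f"pc{k + 1}"] = pcs[:, k]
    return SampleSheet(table)


def _sigmoid2(m: np.ndarray) -> np.ndarray:
    """Inverse of the base-2 M-value transform."""
    return 1.0 / (1.0 + np.exp2(-m))


def simulate_true_betas(manifest: ProbeAnnotation, samples: SampleSheet,
                        config: SimulationConfig,
                        rng: np.random.Generator,
                        probe_rng: np.random.Generator | None = None,
                        ) -> TruthRecord:
    """Draw the biological methylation state for one cohort.

    Plain probes: per-probe mean M-value from a bimodal (hypo/hyper)
    mixture shared across samples, plus per-person Gaussian variation
    on the M-value scale.  DMR probes: beta centred at 0.5 with small
    spread.  SNP probes: Hardy-Weinberg genotypes at ``snp_maf``, beta
    centred at {0.05, 0.5, 0.95} by genotype.  X probes: female mean
    raised above the male mean by ``x_sex_margin``.

    ``probe_rng`` draws the probe-level parameters (per-probe means);
    passing the same ``probe_rng`` for two cohorts makes their biology
    exchangeable, as for cohorts sampled from one population.
    """
    if probe_rng is None:
        probe_rng = rng
    n_probes, n_samples = len(manifest), len(samples)
    cls = manifest.table["special_class"].to_numpy()
    beta = np.empty((n_probes, n_samples))

    # plain probes: bimodal on the M-value scale
    plain = cls == "plain"
    n_plain = int(plain.sum())
    hyper = probe_rng.random(n_plain) < 0.4
    probe_mean_m = np.where(hyper, probe_rng.normal(2.5, 0.8, n_plain),
                            probe_rng.normal(-2.5, 0.8, n_plain))
    person = rng.normal(0.0, config.person_mvalue_sd, (n_plain, n_samples))
    beta[plain] = _sigmoid2(probe_mean_m[:, None] + person)

    # imprinted-DMR probes: hemi-methylated, expected beta 0.5
    dmr = cls == "dmr"
    beta[dmr] = np.clip(
        0.5 + rng.normal(0.0, config.dmr_noise_sd, (int(dmr.sum()), n_samples)),
        0.0, 1.0)

    # SNP-affected probes: trimodal by genotype under Hardy-Weinberg
    snp = cls == "snp"
    n_snp = int(snp.sum())
    geno = rng.binomial(2, config.snp_maf, (n_snp, n_samples))
    centres = np.array([0.05, 0.5, 0.95])
    beta[snp] = np.clip(
        centres[geno] + rng.normal(0.0, 0.01, (n_snp, n_samples)), 0.0, 1.0)

    # X probes hypermethylated in females
    xp = cls == "chrX_sex"
    n_x = int(xp.sum())
    female = (samples.table["sex"] == "F").to_numpy()
    male_mean = probe_rng.uniform(0.15, 0.35, n_x)
    x_mean = male_mean[:, None] + config.x_sex_margin * female[None, :]
    beta[xp] = np.clip(
        x_mean + rng.normal(0.0, 0.03, (n_x, n_samples)), 0.0, 1.0)

    true_beta = pd.DataFrame(beta, index=manifest.probe_ids,
                             columns=samples.sample_ids)
    genotypes = pd.DataFrame(geno, index=manifest.probe_ids[snp],
                             columns=samples.sample_ids)
    return TruthRecord(true_beta=true_beta, genotypes=genotypes)


def render_intensities(truth: TruthRecord, manifest: ProbeAnnotation,
                       samples: SampleSheet, config: SimulationConfig,
                       batch: BatchParams,
                       rng: np.random.Generator) -> IntensityData:
    """Push true betas through the technical model of one batch."""
    beta = truth.true_beta.to_numpy()
    n_probes, n_samples = beta.shape
    is_t2 = manifest.is_type("II")
    chan = manifest.table["channel"].to_numpy()

    mu_log = np.log(config.mean_total_intensity) - config.log_intensity_sd ** 2 / 2
    total = rng.lognormal(mu_log, config.log_intensity_sd,
                          (n_probes, n_samples))
    bg = np.where(is_t2, batch.background_type2,
                  batch.background_type1)[:, None]
    noise_m = rng.normal(0.0, config.noise_sd, (n_probes, n_samples))
    noise_u = rng.normal(0.0, config.noise_sd, (n_probes, n_samples))

    meth = total * beta + bg + noise_m
    unmeth = total * (1.0 - beta) + bg + noise_u

    # dye: Type II reads M in green and U in red; Type I reads both
    # alleles in its declared channel
    dye_m = np.where(is_t2, batch.dye_grn,
                     np.where(chan == "Grn", batch.dye_grn, batch.dye_red))
    dye_u = np.where(is_t2, batch.dye_red,
                     np.where(chan == "Grn", batch.dye_grn, batch.dye_red))
    meth = np.maximum(meth * dye_m[:, None], 0.0)
    unmeth = np.maximum(unmeth * dye_u[:, None], 0.0)

    # out-of-band: background-only signal in the opposite channel
    is_t1 = ~is_t2
    oob = np.full((n_probes, n_samples), np.nan)
    oob_bg = batch.background_type1
    oob_dye = np.where(chan == "Grn", batch.dye_red, batch.dye_grn)
    oob_m = oob.copy()
    oob_u = oob.copy()
    oob_draw_m = np.maximum(
        (oob_bg + rng.normal(0.0, config.noise_sd, (n_probes, n_samples)))
        * oob_dye[:, None], 0.0)
    oob_draw_u = np.maximum(
        (oob_bg + rng.normal(0.0, config.noise_sd, (n_probes, n_samples)))
        * oob_dye[:, None], 0.0)
    oob_m[is_t1] = oob_draw_m[is_t1]
    oob_u[is_t1] = oob_draw_u[is_t1]

    beadcount = rng.poisson(config.beadcount_mean, (n_probes, n_samples)) + 3
    low = rng.random((n_probes, n_samples)) < config.low_bead_rate
    beadcount = np.where(low, rng.integers(0, 3, (n_probes, n_samples)),
                         beadcount)

    fail = rng.random((n_probes, n_samples)) < config.detection_fail_rate
    detp = np.where(fail, rng.uniform(0.05, 1.0, (n_probes, n_samples)),
                    rng.uniform(0.0, 1e-4, (n_probes, n_samples)))

    idx, cols = truth.true_beta.index, truth.true_beta.columns

    def df(a):
        return pd.DataFrame(a, index=idx, columns=cols)

    return IntensityData(
        meth=df(meth), unmeth=df(unmeth),
        annotation=manifest, samples=samples,
        oob_meth=df(oob_m), oob_unmeth=df(oob_u),
        beadcount=df(beadcount.astype(int)), detection_p=df(detp))


def simulate_phenotype(truth: TruthRecord, samples: SampleSheet,
                       config: SimulationConfig, rng: np.random.Generator,
                       causal_ids: list[str] | None = None,
                       weights: pd.Series | None = None,
                       manifest: ProbeAnnotation | None = None,
                       ) -> tuple[SampleSheet, TruthRecord]:
    """Attach a log-normal BMI phenotype with sparse CpG effects.

    log(BMI) = b0 + age*b_age + male*b_sex + pcs.b_pc
               + sum_j w_j * Mval_true_j + eps,
    with w_j ~ Normal(0, effect_sd^2) on ``n_causal`` plain CpGs.
    Passing ``causal_ids``/``weights`` reuses an existing architecture
    (e.g. to phenotype a second cohort under the same genetic model).
    """
    manifest_cls = truth.true_beta.index
    if weights is None:
        if manifest is not None:
            plain_ids = manifest.ids_of_class("plain")
        else:
            plain_ids = truth.true_beta.index[
                ~truth.true_beta.index.isin(truth.genotypes.index)]
        if causal_ids is None:
            if config.n_causal > len(plain_ids):
                raise ValidationError("n_causal exceeds available probes")
            causal_ids = list(rng.choice(plain_ids, size=config.n_causal,
                                         replace=False))
        w = rng.normal(0.0, config.effect_sd, len(causal_ids))
        weights = pd.Series(w, index=causal_ids)
    else:
        causal_ids = list(weights.index)
        if not set(causal_ids) <= set(manifest_cls):
            raise ValidationError("causal ids not present in truth")

    b = truth.true_beta.loc[causal_ids].to_numpy()
    b = np.clip(b, 1e-6, 1 - 1e-6)
    mvals = np.log2(b / (1 - b))
    signal = mvals.T @ weights.to_numpy()

    t = samples.table
    male = (t["sex"] == "M").to_numpy().astype(float)
    pc_cols = samples.pc_columns()
    pcs = t[pc_cols].to_numpy() if pc_cols else np.zeros((len(t), 0))
    b_pc = 0.01 * np.ones(pcs.shape[1])
    covar_part = (0.002 * t["age"].to_numpy() - 0.03 * male + pcs @ b_pc)
    eps = rng.normal(0.0, config.pheno_noise_sd, len(t))
    log_bmi = np.log(27.0) + covar_part + signal + eps

    table = t.copy()
    table["bmi"] = np.exp(log_bmi)
    new_truth = TruthRecord(
        true_beta=truth.true_beta, genotypes=truth.genotypes,
        causal_cpg_ids=list(causal_ids), causal_weights=weights,
        true_signal=pd.Series(signal, index=samples.sample_ids))
    return SampleSheet(table), new_truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full two-cohort study: shared manifest and causal
    architecture, cohort-specific individuals, each cohort rendered
    under its own batch parameters."""
    (rng_manifest, rng_sheet_a, rng_sheet_b, rng_bio, rng_tech,
     rng_pheno) = _stage_rngs(config.seed, 6)

    manifest = simulate_manifest(config, rng_manifest)
    sheet_a = simulate_sample_sheet(config, "CohortA", "batch1", rng_sheet_a,
                                    prefix="A")
    sheet_b = simulate_sample_sheet(config, "CohortB", "batch2", rng_sheet_b,
                                    prefix="B")

    # one probe-parameter stream shared by both cohorts keeps the
    # biology exchangeable; person-level draws differ
    probe_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(7)[6])
    probe_params_seed = probe_rng.integers(0, 2 ** 31)
    truth_a = simulate_true_betas(manifest, sheet_a, config, rng_bio,
                                  np.random.default_rng(probe_params_seed))
    truth_b = simulate_true_betas(manifest, sheet_b, config, rng_bio,
                                  np.random.default_rng(probe_params_seed))

    sheet_a, truth_a = simulate_phenotype(truth_a, sheet_a, config, rng_pheno,
                                          manifest=manifest)
    sheet_b, truth_b = simulate_phenotype(truth_b, sheet_b, config, rng_pheno,
                                          weights=truth_a.causal_weights)

    data_a = render_intensities(truth_a, manifest, sheet_a, config,
                                config.batch_a, rng_tech)
    data_b = render_intensities(truth_b, manifest, sheet_b, config,
                                config.batch_b, rng_tech)
    return SimulatedStudy(config=config, manifest=manifest,
                          cohort_a=data_a, cohort_b=data_b,
                          truth_a=truth_a, truth_b=truth_b)
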