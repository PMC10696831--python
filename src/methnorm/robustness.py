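"""Separate-versus-joint normalisation robustness.

The experiment: take a target cohort and a reference cohort, normalise
the target (1) on its own and (2) jointly with the reference, project
the same EpiScore onto both, and ask how much each individual's score
moved.  Within-array methods are invariant by construction; between-
array methods move scores by an amount that reflects how much the
reference cohort's technical profile leaks into the target's values.

Summary statistics: the median absolute difference (MAD) between the
two arms, Pearson correlations of scores with the phenotype (with
Fisher-z confidence intervals), incremental R^2 over an age + sex
regression, and percentile-rank shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, IntensityData, harmonise_cohorts
from .episcore import EpiScoreModel, project_episcore
from .errors import ValidationError
from .metrics import evaluate_method, rank_methods
from .norm import MethodSpec, get_method, normalise

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedScores:
    """Per-sample EpiScores from the two normalisation arms."""

    table: pd.DataFrame  # sample_id index; score_separate/score_joint/...

    def __post_init__(self):
        need = {"score_separate", "score_joint"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"PairedScores needs columns {need}")


@dataclass(frozen=True)
class EvaluationResult:
    """Per-method robustness and quality summary for a cohort pair."""

    summary: pd.DataFrame                    # method x statistic
    paired: dict[str, PairedScores]
    metric_ranks: pd.DataFrame | None = None
    failures: dict[str, str] = field(default_factory=dict)


def _percentiles(x: np.ndarray) -> np.ndarray:
    """Percentile place 100*(rank - 0.5)/n with average ranks on ties."""
    r = stats.rankdata(x, method="average")
    return 100.0 * (r - 0.5) / len(x)


def separate_vs_joint(target: IntensityData, reference: IntensityData,
                      method: MethodSpec | str, model: EpiScoreModel,
                      project_scale: str = "mvalue") -> PairedScores:
    """Normalise the target alone and jointly with the reference,
    project the EpiScore in both arms, and pair the scores by sample.

    Both arms run on the harmonised probe intersection so that any
    score difference comes from normalisation, not probe content.
    """
    spec = get_method(method) if isinstance(method, str) else method
    combined = harmonise_cohorts([target, reference])
    target_ids = list(target.samples.sample_ids)
    target_h = combined.subset_samples(target_ids)
    betas_sep = normalise(target_h, spec)
    betas_joint = normalise(combined, spec).subset_samples(target_ids)
    return pair_scores(target, betas_sep, betas_joint, model,
                       project_scale=project_scale)


def pair_scores(target: IntensityData, betas_sep: BetaMatrix,
                betas_joint: BetaMatrix, model: EpiScoreModel,
                project_scale: str = "mvalue") -> PairedScores:
    """Project the model onto pre-computed separate/joint betas of the
    same target samples and pair the scores."""

    def project(betas: BetaMatrix) -> pd.Series:
        values = betas.to_mvalues() if project_scale == "mvalue" else betas
        return project_episcore(model, values)

    scores_sep = project(betas_sep)
    scores_joint = project(betas_joint)
    if not scores_sep.index.equals(scores_joint.index):
        raise ValidationError("arms scored different sample sets")

    table = pd.DataFrame({
        "cohort": target.samples.table["cohort"],
        "score_separate": scores_sep,
        "score_joint": scores_joint,
        "percentile_separate": _percentiles(scores_sep.to_numpy()),
        "percentile_joint": _percentiles(scores_joint.to_numpy()),
    })
    if "bmi" in target.samples.table.columns:
        table["phenotype"] = target.samples.table["bmi"]
    return PairedScores(table)


def median_abs_diff(paired: PairedScores) -> float:
    """Median over samples of |score_separate - score_joint|."""
    t = paired.table
    if len(t) == 0:
        raise ValidationError("no samples in paired scores")
    return float(np.median(np.abs(t["score_separate"] - t["score_joint"])))


def pearson_with_ci(scores: pd.Series, phenotype: pd.Series,
                    conf: float = 0.95) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval
    (SE = 1/sqrt(n - 3))."""
    x = scores.to_numpy(dtype=float)
    y = phenotype.loc[scores.index].to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        raise ValidationError("need at least 4 samples for a CI")
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise ValidationError("zero variance input to correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    half = zcrit / np.sqrt(n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def incremental_r2(phenotype: pd.Series, samples, scores: pd.Series,
                   log_transform: bool = True) -> float:
    """Percentage-point gain in R^2 from adding the EpiScore to a
    log(BMI) ~ age + sex regression."""
    t = samples.table.loc[scores.index]
    y = phenotype.loc[scores.index].to_numpy(dtype=float)
    if log_transform:
        if (y <= 0).any():
            raise ValidationError("phenotype must be positive for log")
        y = np.log(y)
    male = (t["sex"] == "M").to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(y)), t["age"].to_numpy(dtype=float),
                            male])
    full = np.column_stack([base, scores.to_numpy(dtype=float)])
    centred = full[:, 1:] - full[:, 1:].mean(axis=0)
    norms = np.linalg.norm(centred, axis=0)
    if (norms < 1e-12).any() or \
            np.linalg.matrix_rank(centred / norms) < centred.shape[1]:
        raise ValidationError("rank-deficient design in incremental R^2")

    def r2(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid ** 2) / tss

    return 100.0 * (r2(full) - r2(base))


def percentile_shift(paired: PairedScores) -> dict:
    """Max and median per-sample percentile-place change between arms,
    plus the Spearman correlation of the two arms."""
    t = paired.table
    if len(t) < 2:
        raise ValidationError("need at least 2 samples")
    shift = np.abs(t["percentile_separate"] - t["percentile_joint"])
    rho = stats.spearmanr(t["score_separate"], t["score_joint"]).statistic
    return {"max_shift": float(shift.max()),
            "median_shift": float(np.median(shift)),
            "spearman": float(rho)}


def full_benchmark(target: IntensityData, reference: IntensityData,
                   methods: list[MethodSpec | str], model: EpiScoreModel,
                   compute_metrics: bool = True,
                   project_scale: str = "mvalue") -> EvaluationResult:
    """Run the separate-vs-joint comparison and quality metrics for a
    list of methods.  A failing method is recorded and skipped, not
    fatal.  Output row order follows the input method order.
    """
    specs = [get_method(m) if isinstance(m, str) else m for m in methods]
    combined = harmonise_cohorts([target, reference])
    target_ids = list(target.samples.sample_ids)
    reference_ids = list(reference.samples.sample_ids)

    rows = {}
    paired_all: dict[str, PairedScores] = {}
    metric_values: dict[str, dict[str, float]] = {}
    failures: dict[str, str] = {}
    for spec in specs:
        try:
            betas_sep_t = normalise(combined.subset_samples(target_ids), spec)
            betas_joint_full = normalise(combined, spec)
            paired = pair_scores(target, betas_sep_t,
                                 betas_joint_full.subset_samples(target_ids),
                                 model, project_scale=project_scale)
            paired_all[spec.name] = paired
            row = {"mad": median_abs_diff(paired)}
            row.update({f"pct_{k}": v
                        for k, v in percentile_shift(paired).items()})
            if "phenotype" in paired.table.columns:
                pheno = paired.table["phenotype"]
                for arm in ("separate", "joint"):
                    r, lo, hi = pearson_with_ci(
                        paired.table[f"score_{arm}"], np.log(pheno))
                    row[f"r_{arm}"] = r
                    row[f"r_{arm}_lo"] = lo
                    row[f"r_{arm}_hi"] = hi
                row["incremental_r2"] = incremental_r2(
                    pheno, target.samples, paired.table["score_separate"])
            if compute_metrics:
                mm = {}
                betas_sep_r = normalise(
                    combined.subset_samples(reference_ids), spec)
                for label, b in (("target", betas_sep_t),
                                 ("reference", betas_sep_r),
                                 ("joint", betas_joint_full)):
                    for k, v in evaluate_method(b).items():
                        mm[f"{k}_{label}"] = v
                metric_values[spec.name] = mm
                row.update(mm)
            rows[spec.name] = row
        except Exception as exc:  # fail-soft sweep
            logger.warning("method %s failed: %s", spec.name, exc)
            failures[spec.name] = f"{type(exc).__name__}: {exc}"
    if not rows:
        raise ValidationError("every method failed; nothing to report")
    summary = pd.DataFrame(rows).T
    summary.index.name = "method"
    metric_ranks = None
    if compute_metrics and len(metric_values) >= 2:
        table = rank_methods(metric_values)
        metric_ranks = table.ranks
        summary["mean_rank"] = table.mean_rank.reindex(summary.index)
    if failures:
        logger.warning("benchmark finished with %d failing methods: %s",
                       len(failures), sorted(failures))
    return EvaluationResult(summary=summary, paired=paired_all,
                            metric_ranks=metric_ranks, failures=failures)
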