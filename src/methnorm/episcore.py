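"""Elastic-net EpiScores: training on a reference cohort, projection
onto any normalised dataset, and de-scaling back to trait units.

An EpiScore is a sparse weighted sum of CpG methylation values trained
to predict a trait.  The training recipe mirrors common practice for
DNAm predictors of BMI: the target is the residual of log(BMI) from an
ordinary least squares regression on age, sex and ancestry principal
components; features are CpG M-values pruned to the most variable
sites; the predictor is an elastic net (mixing parameter alpha = 0.5)
with the penalty strength chosen by 10-fold cross-validation.

External coefficient tables (e.g. a published epigenetic age clock)
are supported through the same :class:`EpiScoreModel` container and
the coefficient-table reader in :mod:`methnorm.io`; no published
weight values are shipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .core import BetaMatrix, MValueMatrix, SampleSheet
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovariateModel:
    """Fitted OLS of log(BMI) on covariates; kept so scores can be
    de-scaled back to kg/m^2."""

    params: pd.Series          # named coefficients incl. const
    columns: list[str]         # covariate columns in design order

    def design(self, samples: SampleSheet) -> pd.DataFrame:
        t = samples.table
        X = pd.DataFrame(index=t.index)
        X["const"] = 1.0
        for c in self.columns:
            if c == "sex_male":
                X[c] = (t["sex"] == "M").astype(float)
            elif c in t.columns:
                X[c] = t[c].astype(float)
            else:
                raise ValidationError(f"covariate column {c!r} missing")
        return X

    def predict(self, samples: SampleSheet) -> pd.Series:
        X = self.design(samples)
        return X @ self.params.reindex(X.columns)


@dataclass(frozen=True)
class TrainingConfig:
    alpha: float = 0.5       # elastic-net mixing (1 = lasso, 0 = ridge)
    n_folds: int = 10
    top_k_sd: int | None = None   # feature pruning; None keeps all
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    max_iter: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be at least 2")


@dataclass(frozen=True)
class EpiScoreModel:
    """Intercept plus sparse CpG weights, with enough metadata to
    project onto new data (training-mean imputation for missing
    probes) and to reproduce the fit."""

    intercept: float
    weights: pd.Series                 # probe_id -> weight, nonzero only
    training_scale: str = "mvalue"     # value scale the weights expect
    feature_means: pd.Series | None = None
    alpha: float | None = None
    selected_lambda: float | None = None
    n_folds: int | None = None
    feature_space_size: int | None = None
    seed: int | None = None


def residualise_phenotype(samples: SampleSheet,
                          phenotype: str = "bmi",
                          log_transform: bool = True,
                          ) -> tuple[pd.Series, CovariateModel]:
    """OLS residuals of log(BMI) on age, sex and ancestry PCs.

    Returns the residual target vector and the fitted covariate model
    (stored for later de-scaling of projected scores).
    """
    t = samples.table
    if phenotype not in t.columns:
        raise ValidationError(f"phenotype column {phenotype!r} missing")
    y = t[phenotype].astype(float)
    if log_transform:
        if (y <= 0).any():
            raise ValidationError("phenotype must be positive for log")
        y = np.log(y)
    cols = ["age", "sex_male"] + samples.pc_columns()
    model = CovariateModel(params=pd.Series(dtype=float), columns=cols)
    X = model.design(samples)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValidationError(
            f"rank-deficient covariate design (suspect columns {worst})")
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    params = pd.Series(fit.params, index=X.columns)
    resid = pd.Series(y.to_numpy() - X.to_numpy() @ fit.params,
                      index=t.index, name="target")
    return resid, CovariateModel(params=params, columns=cols)


def top_sd_features(mvalues: MValueMatrix, k: int) -> list[str]:
    """The k probes with the largest across-sample standard deviation;
    ties broken lexicographically by probe id for determinism."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(mvalues.values):
        raise ValidationError("k exceeds the number of probes")
    sds = mvalues.values.std(axis=1, ddof=1)
    order = sorted(sds.index, key=lambda pid: (-sds[pid], pid))
    return order[:k]


def fit_elastic_net_cv(mvalues: MValueMatrix, target: pd.Series,
                       config: TrainingConfig | None = None) -> EpiScoreModel:
    """Cross-validated elastic net of the residualised trait on CpG
    M-values.

    Features are standardised internally; the returned weights are on
    the raw M-value scale so projection is a plain dot product.  The
    penalty path is ``n_lambdas`` log-spaced values from the analytic
    lambda_max down by ``lambda_min_ratio``; the model at the CV-mean-
    squared-error minimum is returned.
    """
    config = config or TrainingConfig()
    if config.top_k_sd is not None:
        keep = top_sd_features(mvalues, config.top_k_sd)
        X_df = mvalues.values.loc[keep]
    else:
        X_df = mvalues.values
    common = X_df.columns.intersection(target.index)
    if len(common) != len(X_df.columns) or len(common) != len(target):
        raise ValidationError("samples of matrix and target do not align")
    y = target.loc[X_df.columns].to_numpy(dtype=float)
    if len(y) < config.n_folds:
        raise ValidationError("need at least n_folds samples")
    X = X_df.to_numpy(dtype=float).T          # samples x features
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mu) / sd_safe

    cv = KFold(n_splits=config.n_folds, shuffle=True,
               random_state=config.seed)
    enet = ElasticNetCV(l1_ratio=config.alpha, alphas=config.n_lambdas,
                        eps=config.lambda_min_ratio, cv=cv,
                        max_iter=config.max_iter, random_state=config.seed)
    enet.fit(Xs, y)
    w_std = enet.coef_
    nz = np.flatnonzero(w_std != 0)
    if len(nz) == 0:
        logger.warning("elastic net selected no features; intercept-only "
                       "model returned")
    w_raw = w_std / sd_safe
    intercept = float(enet.intercept_ - np.sum(w_std * mu / sd_safe))
    probe_ids = X_df.index.to_numpy()
    weights = pd.Series(w_raw[nz], index=probe_ids[nz], name="weight")
    means = pd.Series(mu[nz], index=probe_ids[nz], name="training_mean")
    return EpiScoreModel(
        intercept=intercept, weights=weights, training_scale="mvalue",
        feature_means=means, alpha=config.alpha,
        selected_lambda=float(enet.alpha_), n_folds=config.n_folds,
        feature_space_size=X_df.shape[0], seed=config.seed)


def project_episcore(model: EpiScoreModel,
                     data: BetaMatrix | MValueMatrix,
                     missing_threshold: float = 0.2) -> pd.Series:
    """score = intercept + sum_j w_j * value_j per sample.

    Model probes absent from ``data`` are imputed at their training
    mean (count logged); more than ``missing_threshold`` of them
    missing is an error.  A mismatch between the model's declared
    training scale and the data's scale is warned about, not blocked —
    projection onto either scale is a legitimate, documented choice.
    """
    if data.scale != model.training_scale:
        logger.warning("projecting a %s-trained model onto %s values",
                       model.training_scale, data.scale)
    if len(model.weights) == 0:
        return pd.Series(model.intercept, index=data.values.columns,
                         name="episcore")
    present = model.weights.index.intersection(data.values.index)
    n_missing = len(model.weights) - len(present)
    if n_missing:
        frac = n_missing / len(model.weights)
        if frac > missing_threshold:
            raise ValidationError(
                f"{n_missing}/{len(model.weights)} model probes missing "
                f"({frac:.1%} > {missing_threshold:.0%})")
        logger.warning("%d model probes missing (%.1f%%); imputed at "
                       "training mean", n_missing, 100 * frac)
    scores = np.full(data.values.shape[1], model.intercept)
    if len(present):
        w = model.weights.loc[present].to_numpy()
        scores = scores + data.values.loc[present].to_numpy().T @ w
    if n_missing:
        missing = model.weights.index.difference(present)
        if model.feature_means is not None:
            fill = model.feature_means.reindex(missing).fillna(0.0)
        else:
            logger.warning("model carries no training means; missing "
                           "probes imputed at 0")
            fill = pd.Series(0.0, index=missing)
        scores = scores + float(
            (model.weights.loc[missing] * fill).sum())
    return pd.Series(scores, index=data.values.columns, name="episcore")


def descale_scores(scores: pd.Series, covariate_model: CovariateModel,
                   samples: SampleSheet) -> pd.Series:
    """Map residual-scale scores back to approximate kg/m^2:
    descaled = exp(score + covariate prediction).

    For small score differences the delta method gives
    d(kg/m^2) ~= BMI * d(score).
    """
    pred = covariate_model.predict(samples).loc[scores.index]
    return np.exp(scores + pred).rename("bmi_descaled")
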