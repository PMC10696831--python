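"""Normalisation quality metrics and rank aggregation.

Three metrics score how well a normalised dataset preserves known
biological structure:

* **DMRSE** — the standard error of beta at imprinted differentially
  methylated regions, where hemi-methylation fixes the expectation at
  0.5: SD of the DMR betas divided by sqrt(n_samples).  Lower is
  better.
* **GCOSE** — at probes overlapping common SNPs, betas form three
  genotype clusters; the metric k-means-clusters each probe's betas
  into three groups, takes the mean squared error about each cluster
  centre, and averages the three.  Lower is better.
* **Seabird** — the AUC of a sex classifier scoring each sample by its
  mean X-chromosome beta (X probes hypermethylated in females).
  Higher is better; the metric table stores 1 - AUC so that lower is
  uniformly better.

Methods are ranked on each metric and the ranks averaged into a mean
overall rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import BetaMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["dmrse", "gcose", "seabird"]


def dmrse(betas: BetaMatrix, dmr_ids: Iterable[str] | None = None,
          mode: str = "pooled") -> float:
    """Imprinted-DMR standard error.

    mode="pooled" (default) pools every DMR beta across probes and
    samples into one SD; mode="per_probe" computes SD/sqrt(n) per probe
    and averages.
    """
    if dmr_ids is None:
        dmr_ids = betas.annotation.ids_of_class("dmr")
    dmr_ids = pd.Index(dmr_ids)
    if len(dmr_ids) == 0:
        raise ValidationError("no DMR probes supplied")
    missing = ~dmr_ids.isin(betas.values.index)
    if missing.any():
        raise ValidationError(f"{missing.sum()} DMR ids absent from data")
    x = betas.values.loc[dmr_ids].to_numpy()
    n_samples = x.shape[1]
    if mode == "pooled":
        return float(np.std(x, ddof=1) / np.sqrt(n_samples))
    if mode == "per_probe":
        return float(np.mean(np.std(x, axis=1, ddof=1)) / np.sqrt(n_samples))
    raise ValidationError(f"unknown DMRSE mode {mode!r}")


def _kmeans_1d(x: np.ndarray, centres: np.ndarray,
               max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's algorithm in one dimension with fixed initial centres.
    Empty clusters keep their current centre."""
    c = centres.astype(float).copy()
    for _ in range(max_iter):
        assign = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
        new_c = c.copy()
        for k in range(len(c)):
            sel = assign == k
            if sel.any():
                new_c[k] = x[sel].mean()
        if np.allclose(new_c, c):
            c = new_c
            break
        c = new_c
    assign = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
    return assign, c


def gcose(betas: BetaMatrix, snp_ids: Iterable[str] | None = None,
          k: int = 3,
          init_centres: tuple[float, ...] = (0.1, 0.5, 0.9)) -> float:
    """Genotype-cluster standard error at SNP-affected probes.

    Per probe: cluster betas across samples into ``k`` genotype groups
    (1-D k-means initialised at the canonical beta levels), take the
    MSE about each occupied cluster centre, average those; the final
    statistic averages over probes.  Probes with fewer than k distinct
    values are skipped with a warning.
    """
    if snp_ids is None:
        snp_ids = betas.annotation.ids_of_class("snp")
    snp_ids = pd.Index(snp_ids)
    if len(snp_ids) == 0:
        raise ValidationError("no SNP probes supplied")
    x = betas.values.loc[snp_ids].to_numpy()
    centres0 = np.asarray(init_centres, dtype=float)
    if len(centres0) != k:
        raise ValidationError("init_centres length must equal k")
    per_probe = []
    n_skipped = 0
    for row in x:
        if len(np.unique(row)) < k:
            n_skipped += 1
            continue
        assign, c = _kmeans_1d(row, centres0)
        mses = [np.mean((row[assign == j] - c[j]) ** 2)
                for j in range(k) if (assign == j).any()]
        per_probe.append(np.mean(mses))
    if n_skipped:
        logger.warning("GCOSE: %d probes skipped (fewer than %d distinct "
                       "values)", n_skipped, k)
    if not per_probe:
        raise ValidationError("all SNP probes skipped; GCOSE undefined")
    return float(np.mean(per_probe))


def seabird_auc(betas: BetaMatrix, x_ids: Iterable[str] | None = None,
                sex: pd.Series | None = None) -> float:
    """AUC of the X-chromosome sex predictor.

    Each sample is scored by its mean beta over the sex-differentiated
    X probes; the AUC classifies female (positive class, hypermethylated)
    versus male, with tied scores counted 0.5.
    """
    if x_ids is None:
        x_ids = betas.annotation.ids_of_class("chrX_sex")
    x_ids = pd.Index(x_ids)
    if len(x_ids) == 0:
        raise ValidationError("no X-chromosome probes supplied")
    if sex is None:
        sex = betas.samples.table["sex"]
    sex = sex.loc[betas.values.columns]
    y = (sex == "F").to_numpy().astype(int)
    if y.all() or not y.any():
        raise ValidationError("both sexes required for the Seabird metric")
    scores = betas.values.loc[x_ids].mean(axis=0).to_numpy()
    return float(roc_auc_score(y, scores))


@dataclass(frozen=True)
class MetricTable:
    """Per-method metric values (lower = better everywhere; seabird is
    stored as 1 - AUC), their per-column ranks, and the mean rank."""

    values: pd.DataFrame
    ranks: pd.DataFrame
    mean_rank: pd.Series


def evaluate_method(betas: BetaMatrix, dmrse_mode: str = "pooled") -> dict:
    """All three metrics for one normalised dataset, with seabird
    already flipped to 1 - AUC."""
    return {
        "dmrse": dmrse(betas, mode=dmrse_mode),
        "gcose": gcose(betas),
        "seabird": 1.0 - seabird_auc(betas),
    }


def rank_methods(metrics: Mapping[str, Mapping[str, float]]) -> MetricTable:
    """Aggregate per-method metric values into ranks and a mean rank.

    ``metrics`` maps method name -> {metric -> value}; columns beyond
    the three standard metrics are allowed (e.g. the same metric on
    several datasets) and participate in the mean rank.  Missing values
    rank last with a warning.  Output rows are sorted by mean rank
    (stable order for ties).
    """
    if len(metrics) < 2:
        raise ValidationError("ranking needs at least two methods")
    values = pd.DataFrame(metrics).T
    if values.isna().any().any():
        logger.warning("missing metric values ranked last")
    ranks = values.rank(axis=0, method="average", na_option="bottom")
    mean_rank = ranks.mean(axis=1)
    order = mean_rank.sort_values(kind="stable").index
    return MetricTable(values=values.loc[order], ranks=ranks.loc[order],
                       mean_rank=mean_rank.loc[order])
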