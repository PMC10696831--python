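"""Between-array normalisation methods beyond the combinatorial family:
functional normalisation (control-summary principal components) and
subset quantile normalisation onto Type I anchors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ..core import BetaMatrix, IntensityData, beta_from_intensities
from ..errors import CapabilityError, ValidationError
from .quantile import quantile_normalise

logger = logging.getLogger(__name__)

_SUMMARY_QUANTILES = np.array([0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99])


def control_summaries(data: IntensityData) -> pd.DataFrame:
    """Per-sample technical summary measures, derived from out-of-band
    (background-only) intensities: a quantile sketch, mean and sd per
    oob matrix.  These play the role of the array's internal control
    probes, which are hardware-specific and not part of the data model.
    """
    if data.oob_meth is None or data.oob_unmeth is None:
        raise CapabilityError("control summaries need out-of-band matrices")
    is_t1 = data.annotation.is_type("I")
    rows = []
    for name, mat in (("oobM", data.oob_meth), ("oobU", data.oob_unmeth)):
        x = mat.to_numpy(dtype=float)[is_t1]
        q = np.quantile(x, _SUMMARY_QUANTILES, axis=0)
        rows.append(pd.DataFrame(
            q.T, index=mat.columns,
            columns=[f"{name}_q{int(p * 100)}" for p in _SUMMARY_QUANTILES]))
        rows.append(pd.DataFrame({f"{name}_mean": x.mean(axis=0),
                                  f"{name}_sd": x.std(axis=0, ddof=1)},
                                 index=mat.columns))
    return pd.concat(rows, axis=1)


def _principal_components(summaries: pd.DataFrame, n_pcs: int) -> np.ndarray:
    z = summaries.to_numpy(dtype=float)
    z = z - z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    z = z / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def _adjust_by_quantile_regression(mat: np.ndarray, pcs: np.ndarray,
                                   probs: np.ndarray) -> np.ndarray:
    """Remove the control-PC effect from each sample's quantile curve,
    then map values onto the adjusted curve by interpolation."""
    n_probes, n_samples = mat.shape
    qcurves = np.quantile(mat, probs, axis=0)          # probs x samples
    design = np.column_stack([np.ones(n_samples), pcs])
    coef, *_ = np.linalg.lstsq(design, qcurves.T, rcond=None)
    fitted = design @ coef                              # samples x probs
    adjusted = qcurves.T - (fitted - coef[0][None, :])  # keep intercept
    adjusted = np.maximum.accumulate(adjusted, axis=1)  # enforce monotone
    out = np.empty_like(mat, dtype=float)
    for j in range(n_samples):
        out[:, j] = np.interp(mat[:, j], qcurves[:, j], adjusted[j])
    return out


def funnorm_normalise(data: IntensityData, n_pcs: int = 2,
                      n_quantiles: int = 500,
                      offset: float = 100.0) -> BetaMatrix:
    """Functional normalisation: regress each intensity quantile level
    on the first ``n_pcs`` principal components of the per-sample
    control summaries and remove the fitted technical effect, per
    design type; betas from the adjusted intensities.
    """
    if data.n_samples <= n_pcs:
        raise ValidationError("need more samples than control PCs")
    probs = np.linspace(0.0, 1.0, n_quantiles)
    if n_pcs == 0:
        pcs = np.zeros((data.n_samples, 0))
    else:
        pcs = _principal_components(control_summaries(data), n_pcs)
    is_t1 = data.annotation.is_type("I")
    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    for mat in (meth, unmeth):
        for mask in (is_t1, ~is_t1):
            if mask.sum() >= 2:
                mat[mask] = _adjust_by_quantile_regression(
                    mat[mask], pcs, probs)
    idx, cols = data.meth.index, data.meth.columns
    adjusted = data.with_signal(pd.DataFrame(meth, index=idx, columns=cols),
                                pd.DataFrame(unmeth, index=idx, columns=cols))
    return beta_from_intensities(adjusted, offset=offset)


def tost_normalise(data: IntensityData, anchor_policy: str = "cpg_count",
                   offset: float = 100.0,
                   return_intensities: bool = False
                   ) -> BetaMatrix | IntensityData:
    """Subset quantile normalisation: map Type II intensities onto the
    distribution of Type I 'anchor' probes, stratified by CpG content
    (default policy); Type I probes are quantile-normalised across
    samples.
    """
    if anchor_policy not in ("cpg_count", "all"):
        raise ValidationError(f"unknown anchor policy {anchor_policy!r}")
    ann = data.annotation
    is_t1 = ann.is_type("I")
    if not is_t1.any() or not (~is_t1).any():
        raise CapabilityError("Tost needs both probe types")
    cpg = ann.table["cpg_count"].to_numpy()
    strata = sorted(np.unique(cpg)) if anchor_policy == "cpg_count" else [None]

    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    n_samples = meth.shape[1]
    for c in strata:
        if c is None:
            anchors = np.flatnonzero(is_t1)
            targets = np.flatnonzero(~is_t1)
        else:
            anchors = np.flatnonzero(is_t1 & (cpg == c))
            targets = np.flatnonzero(~is_t1 & (cpg == c))
        if len(targets) == 0:
            continue
        if len(anchors) < 2:
            logger.warning("no Type I anchors for cpg_count=%s; using all "
                           "Type I probes", c)
            anchors = np.flatnonzero(is_t1)
        for mat in (meth, unmeth):
            for j in range(n_samples):
                anchor_sorted = np.sort(mat[anchors, j])
                pa = (np.arange(len(anchors)) + 0.5) / len(anchors)
                q = (rankdata(mat[targets, j], method="average") - 0.5) \
                    / len(targets)
                mat[targets, j] = np.interp(q, pa, anchor_sorted)

    idx, cols = data.meth.index, data.meth.columns
    meth_df = pd.DataFrame(meth, index=idx, columns=cols)
    unmeth_df = pd.DataFrame(unmeth, index=idx, columns=cols)
    if n_samples > 1:
        t1_ids = idx[is_t1]
        meth_df.loc[t1_ids] = quantile_normalise(meth_df.loc[t1_ids])
        unmeth_df.loc[t1_ids] = quantile_normalise(unmeth_df.loc[t1_ids])
    adjusted = data.with_signal(meth_df, unmeth_df)
    if return_intensities:
        return adjusted
    return beta_from_intensities(adjusted, offset=offset)
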