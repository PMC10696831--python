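"""Quantile-based normalisation primitives.

These are the building blocks the combinatorial between-array methods
compose: classic across-sample quantile normalisation (optionally
stratified by probe type), per-sample background equalisation between
Type I and Type II probes, and per-sample dye-bias correction between
the green and red channels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ..core import IntensityData
from ..errors import ValidationError

logger = logging.getLogger(__name__)


def _qn_one_group(x: np.ndarray) -> np.ndarray:
    """Across-column quantile normalisation of a features x samples
    block.  Each column's values are replaced by the mean order
    statistic at their rank; tied values map to the mean of the target
    values their tie block spans."""
    n, m = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = target
        # average target over ties so equal inputs stay equal
        if np.unique(col).size != n:
            assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    return out


def quantile_normalise(matrix: pd.DataFrame,
                       feature_groups: pd.Series | None = None
                       ) -> pd.DataFrame:
    """Quantile-normalise columns, optionally within feature groups.

    ``feature_groups`` partitions the rows (e.g. by probe design type);
    each group is normalised to its own mean order-statistic
    distribution.  Within-column ranks are preserved.
    """
    if matrix.shape[1] < 1:
        raise ValidationError("need at least one column")
    x = matrix.to_numpy(dtype=float)
    out = np.empty_like(x)
    if feature_groups is None:
        out = _qn_one_group(x)
    else:
        groups = np.asarray(feature_groups.loc[matrix.index])
        for g in pd.unique(groups):
            mask = groups == g
            if mask.sum() < 2:
                raise ValidationError(
                    f"feature group {g!r} has fewer than 2 features")
            out[mask] = _qn_one_group(x[mask])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def background_equalise(data: IntensityData,
                        percentile: float = 5.0) -> IntensityData:
    """Shift Type I intensities so their per-sample background level
    (5th percentile) matches Type II's, separately for the M and U
    signals; results are floored at 0.

    Type I and Type II chemistries sit on different background levels;
    this additive per-sample adjustment removes the offset without
    touching the shape of either distribution.
    """
    t1 = data.annotation.is_type("I")
    t2 = data.annotation.is_type("II")
    if not t1.any() or not t2.any():
        logger.warning("only one probe type present: background "
                       "equalisation is a no-op")
        return data

    def adjust(mat: pd.DataFrame) -> pd.DataFrame:
        x = mat.to_numpy(dtype=float).copy()
        p1 = np.percentile(x[t1], percentile, axis=0)
        p2 = np.percentile(x[t2], percentile, axis=0)
        x[t1] = np.maximum(x[t1] + (p2 - p1)[None, :], 0.0)
        return pd.DataFrame(x, index=mat.index, columns=mat.columns)

    return data.with_signal(adjust(data.meth), adjust(data.unmeth))


def _equalise_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map two samples' worth of values onto the average of their two
    quantile functions, so both come out with the same distribution."""
    na, nb = len(a), len(b)
    sa, sb = np.sort(a), np.sort(b)
    pa = (np.arange(na) + 0.5) / na
    pb = (np.arange(nb) + 0.5) / nb
    qa = (rankdata(a, method="average") - 0.5) / na
    qb = (rankdata(b, method="average") - 0.5) / nb
    a_new = 0.5 * (np.interp(qa, pa, sa) + np.interp(qa, pb, sb))
    b_new = 0.5 * (np.interp(qb, pa, sa) + np.interp(qb, pb, sb))
    return a_new, b_new


def channel_of_signals(data: IntensityData) -> tuple[np.ndarray, np.ndarray]:
    """Colour channel of the M and U signal of every probe.

    Type II probes read M in green and U in red; both alleles of a
    Type I probe are read in the probe's declared channel.
    """
    chan = data.annotation.table["channel"].to_numpy()
    is_t2 = data.annotation.is_type("II")
    m_chan = np.where(is_t2, "Grn", chan)
    u_chan = np.where(is_t2, "Red", chan)
    return m_chan, u_chan


def dye_bias_correct(data: IntensityData, mode: str = "t") -> IntensityData:
    """Equalise green- and red-channel intensity distributions within
    each sample by cross-channel quantile matching.

    mode="t" pools Type I and Type II probes into one correction;
    mode="s" corrects within each design type separately.  The
    operation uses only the sample's own values, so it is within-array.
    """
    if mode not in ("s", "t"):
        raise ValidationError(f"unknown dye-bias mode {mode!r}; use 's' or 't'")
    m_chan, u_chan = channel_of_signals(data)
    is_t2 = data.annotation.is_type("II")
    groups = [np.ones(len(is_t2), bool)] if mode == "t" else [~is_t2, is_t2]

    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    n_samples = meth.shape[1]
    for g in groups:
        if not g.any():
            continue
        m_grn = g & (m_chan == "Grn")
        m_red = g & (m_chan == "Red")
        u_grn = g & (u_chan == "Grn")
        u_red = g & (u_chan == "Red")
        n_grn = m_grn.sum() + u_grn.sum()
        n_red = m_red.sum() + u_red.sum()
        if n_grn == 0 or n_red == 0:
            logger.warning("a design group lacks one channel entirely; "
                           "dye correction skipped for it")
            continue
        for j in range(n_samples):
            grn = np.concatenate([meth[m_grn, j], unmeth[u_grn, j]])
            red = np.concatenate([meth[m_red, j], unmeth[u_red, j]])
            grn_new, red_new = _equalise_pair(grn, red)
            k = m_grn.sum()
            meth[m_grn, j] = grn_new[:k]
            unmeth[u_grn, j] = grn_new[k:]
            k = m_red.sum()
            meth[m_red, j] = red_new[:k]
            unmeth[u_red, j] = red_new[k:]

    idx, cols = data.meth.index, data.meth.columns
    return data.with_signal(pd.DataFrame(meth, index=idx, columns=cols),
                            pd.DataFrame(unmeth, index=idx, columns=cols))
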