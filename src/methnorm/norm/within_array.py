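"""Within-array (sample-wise) normalisation methods.

Each method here uses only a single sample's values, so normalising a
sample alone or inside any cohort yields bit-identical output.  That
invariance is load-bearing for the robustness analysis and is enforced
by tests; keep every computation in this module strictly column-wise.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc, betaincinv, gammaln

from ..core import BetaMatrix, IntensityData, beta_from_intensities
from ..errors import CapabilityError, ConvergenceError, ValidationError
from .quantile import channel_of_signals

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SWAN

def _swan_subset_rng(sample_id: str, stratum: int) -> np.random.Generator:
    """Deterministic per-sample, per-stratum RNG via a stable hash, so
    the 'random' subset does not depend on cohort composition."""
    key = zlib.crc32(f"{sample_id}|{stratum}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(key)


def _swan_map(values: np.ndarray, sub_sorted: np.ndarray,
              avg_sorted: np.ndarray) -> np.ndarray:
    """Map values through their within-type subset quantile onto the
    averaged subset distribution.  Values beyond the subset range are
    shifted by the endpoint offset rather than clamped."""
    k = len(sub_sorted)
    p = (np.arange(k) + 0.5) / k
    q = np.interp(values, sub_sorted, p)
    out = np.interp(q, p, avg_sorted)
    lo, hi = sub_sorted[0], sub_sorted[-1]
    below = values < lo
    above = values > hi
    out[below] = values[below] + (avg_sorted[0] - lo)
    out[above] = values[above] + (avg_sorted[-1] - hi)
    return out


def swan_normalise(data: IntensityData, offset: float = 100.0) -> BetaMatrix:
    """Subset-within-array normalisation.

    Per sample: draw equal numbers of Type I and Type II probes within
    each CpG-content stratum, average the two design types' subset
    quantile distributions, and interpolate every probe's intensity
    onto the averaged distribution.  Applied to the M and U signals
    separately; betas are computed from the adjusted intensities.
    """
    ann = data.annotation.table
    is_t1 = data.annotation.is_type("I")
    is_t2 = ~is_t1
    if not is_t1.any() or not is_t2.any():
        raise CapabilityError("SWAN needs both probe types")
    cpg = ann["cpg_count"].to_numpy()
    strata = sorted(np.unique(cpg))

    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    sample_ids = list(data.meth.columns)
    idx1 = np.flatnonzero(is_t1)
    idx2 = np.flatnonzero(is_t2)

    for j, sid in enumerate(sample_ids):
        sub1_parts, sub2_parts = [], []
        for c in strata:
            c1 = idx1[cpg[idx1] == c]
            c2 = idx2[cpg[idx2] == c]
            k = min(len(c1), len(c2))
            if k == 0:
                logger.warning("SWAN stratum cpg_count=%s empty for one "
                               "type; skipped", c)
                continue
            rng = _swan_subset_rng(sid, int(c))
            sub1_parts.append(rng.choice(c1, size=k, replace=False))
            sub2_parts.append(rng.choice(c2, size=k, replace=False))
        if not sub1_parts:
            raise ValidationError("no usable SWAN strata")
        sub1 = np.concatenate(sub1_parts)
        sub2 = np.concatenate(sub2_parts)
        for mat in (meth, unmeth):
            s1 = np.sort(mat[sub1, j])
            s2 = np.sort(mat[sub2, j])
            avg = 0.5 * (s1 + s2)
            mat[idx1, j] = _swan_map(mat[idx1, j], s1, avg)
            mat[idx2, j] = _swan_map(mat[idx2, j], s2, avg)

    idx, cols = data.meth.index, data.meth.columns
    adjusted = data.with_signal(pd.DataFrame(meth, index=idx, columns=cols),
                                pd.DataFrame(unmeth, index=idx, columns=cols))
    return beta_from_intensities(adjusted, offset=offset)


# ---------------------------------------------------------------------------
# BMIQ

_BETA_CLIP = 1e-6


def _beta_params(mean: np.ndarray, var: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments beta parameters from component mean/variance."""
    var = np.minimum(var, mean * (1 - mean) * 0.999)
    var = np.maximum(var, 1e-6)
    nu = mean * (1 - mean) / var - 1.0
    return np.maximum(mean * nu, 1e-2), np.maximum((1 - mean) * nu, 1e-2)


def _beta_logpdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return ((a - 1) * np.log(x) + (b - 1) * np.log1p(-x)
            + gammaln(a + b) - gammaln(a) - gammaln(b))


def fit_beta_mixture(x: np.ndarray, max_iter: int = 500,
                     tol: float = 1e-5) -> dict:
    """EM fit of a 3-state (unmethylated / hemi / methylated) beta
    mixture, initialised at state means (0.1, 0.5, 0.9).

    Returns component weights, (a, b) parameters, per-point state
    assignments (max posterior) and the iteration count.
    """
    x = np.clip(x, _BETA_CLIP, 1 - _BETA_CLIP)
    means = np.array([0.1, 0.5, 0.9])
    var = np.full(3, 0.005)
    a, b = _beta_params(means, var)
    w = np.full(3, 1.0 / 3.0)
    prev_ll = -np.inf
    trace = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.stack([_beta_logpdf(x, a[k], b[k]) + np.log(w[k])
                         for k in range(3)])
        mx = logp.max(axis=0)
        p = np.exp(logp - mx)
        tot = p.sum(axis=0)
        ll = float(np.sum(mx + np.log(tot)))
        trace.append(ll)
        resp = p / tot
        w = resp.mean(axis=1)
        w = np.maximum(w, 1e-8)
        means = resp @ x / (w * len(x))
        var = np.array([np.average((x - means[k]) ** 2, weights=resp[k])
                        for k in range(3)])
        means = np.clip(means, 1e-3, 1 - 1e-3)
        if (var < 1e-8).any():
            logger.warning("degenerate beta-mixture component; fit stopped")
            break
        a, b = _beta_params(means, var)
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            break
        prev_ll = ll
    else:
        raise ConvergenceError(
            f"beta-mixture EM did not converge in {max_iter} iterations",
            n_iter=n_iter, loglik_trace=trace)
    # reorder components so 0 = unmethylated, 1 = hemi, 2 = methylated
    order = np.argsort(means)
    inv = np.empty(3, int)
    inv[order] = np.arange(3)
    assign = inv[np.argmax(resp, axis=0)]
    return {"w": w[order], "a": a[order], "b": b[order],
            "means": means[order], "assign": assign, "n_iter": n_iter}


def _bmiq_one_sample(beta: np.ndarray, is_t1: np.ndarray) -> np.ndarray:
    x = np.clip(beta, _BETA_CLIP, 1 - _BETA_CLIP)
    b1 = x[is_t1]
    b2 = x[~is_t1]
    fit1 = fit_beta_mixture(b1)
    fit2 = fit_beta_mixture(b2)
    out2 = b2.copy()

    s2 = fit2["assign"]
    # unmethylated state: quantile-map onto the Type I U component
    for state, comp in ((0, 0), (2, 2)):
        sel = s2 == state
        if not sel.any():
            logger.warning("BMIQ: Type II state %d empty; left unchanged",
                           state)
            continue
        p = betainc(fit2["a"][comp], fit2["b"][comp], b2[sel])
        p = np.clip(p, 1e-12, 1 - 1e-12)
        out2[sel] = betaincinv(fit1["a"][comp], fit1["b"][comp], p)

    # hemi-methylated state: affine rescale between the transformed
    # state boundaries, preserving order and continuity
    mid = s2 == 1
    if mid.any():
        left_old = b2[s2 == 0].max() if (s2 == 0).any() else b2[mid].min()
        right_old = b2[s2 == 2].min() if (s2 == 2).any() else b2[mid].max()
        left_new = out2[s2 == 0].max() if (s2 == 0).any() else left_old
        right_new = out2[s2 == 2].min() if (s2 == 2).any() else right_old
        span_old = right_old - left_old
        if span_old > 1e-9:
            out2[mid] = left_new + (b2[mid] - left_old) * \
                (right_new - left_new) / span_old
        # if the middle band has no width there is nothing to rescale

    out = x.copy()
    out[~is_t1] = np.clip(out2, 0.0, 1.0)
    return out


def bmiq_normalise(betas: BetaMatrix) -> BetaMatrix:
    """Beta-mixture quantile normalisation.

    Per sample: fit a 3-state beta mixture to each design type, then
    map Type II probes in the unmethylated and methylated states onto
    the corresponding Type I component distributions by quantile
    transform; hemi-methylated probes are rescaled affinely between the
    transformed boundaries.  Type I probes are untouched.
    """
    is_t1 = betas.annotation.is_type("I")
    if not is_t1.any() or not (~is_t1).any():
        raise CapabilityError("BMIQ needs both probe types")
    x = betas.values.to_numpy(dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        try:
            out[:, j] = _bmiq_one_sample(x[:, j], is_t1)
        except ConvergenceError:
            raise
    return BetaMatrix(pd.DataFrame(out, index=betas.values.index,
                                   columns=betas.values.columns),
                      betas.annotation, betas.samples)


# ---------------------------------------------------------------------------
# Peak-based correction

def _kde_peak(values: np.ndarray, grid_lo: float, grid_hi: float,
              n_grid: int = 512) -> float | None:
    """Location of the density maximum on [grid_lo, grid_hi], Gaussian
    KDE with Silverman bandwidth; None when the side is too sparse."""
    if len(values) < 10 or np.std(values) < 1e-9:
        return None
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(grid_lo, grid_hi, n_grid)
    return float(grid[np.argmax(kde(grid))])


def pbc_normalise(betas: BetaMatrix) -> BetaMatrix:
    """Peak-based correction.

    Per sample: estimate the unmethylated (negative) and methylated
    (positive) M-value density peaks per design type, rescale Type II
    M-values linearly on each side so its peaks land on the Type I
    peaks, and transform back to beta.
    """
    is_t1 = betas.annotation.is_type("I")
    if not is_t1.any() or not (~is_t1).any():
        raise CapabilityError("PBC needs both probe types")
    b = np.clip(betas.values.to_numpy(dtype=float), _BETA_CLIP, 1 - _BETA_CLIP)
    m = np.log2(b / (1 - b))
    out = m.copy()
    for j in range(m.shape[1]):
        m1, m2 = m[is_t1, j], m[~is_t1, j]
        col = out[~is_t1, j]
        for sign in (-1, 1):
            v1 = m1[sign * m1 > 0]
            v2 = m2[sign * m2 > 0]
            if len(v1) == 0 or len(v2) == 0:
                logger.warning("PBC: empty side (sign=%d); rescale skipped",
                               sign)
                continue
            lo, hi = (min(v1.min(), v2.min(), -0.1), 0) if sign < 0 else \
                     (0, max(v1.max(), v2.max(), 0.1))
            p1 = _kde_peak(v1, lo, hi)
            p2 = _kde_peak(v2, lo, hi)
            if p1 is None or p2 is None or abs(p2) < 1e-6:
                logger.warning("PBC: peakless side (sign=%d); rescale "
                               "skipped", sign)
                continue
            sel = sign * m2 > 0
            col[sel] = m2[sel] * (p1 / p2)
        out[~is_t1, j] = col
    beta_out = np.exp2(out) / (1.0 + np.exp2(out))
    return BetaMatrix(pd.DataFrame(np.clip(beta_out, 0.0, 1.0),
                                   index=betas.values.index,
                                   columns=betas.values.columns),
                      betas.annotation, betas.samples)


# ---------------------------------------------------------------------------
# Noob

def _normexp_signal(x: np.ndarray, mu: float, sd: float,
                    alpha: float) -> np.ndarray:
    """Posterior-mean true signal under the normal + exponential
    convolution model; strictly positive."""
    sd = max(sd, 1e-6)
    alpha = max(alpha, 10.0)
    mu_sf = x - mu - sd ** 2 / alpha
    z = mu_sf / sd
    # phi(z)/Phi(z) computed stably via log
    log_ratio = stats.norm.logpdf(z) - stats.norm.logcdf(z)
    signal = mu_sf + sd * np.exp(log_ratio)
    return np.maximum(signal, 1e-6)


def noob_normalise(data: IntensityData,
                   dye_equalise: bool = True) -> IntensityData:
    """Normal-exponential background correction using out-of-band
    Type I intensities, followed by per-sample dye equalisation.

    Per sample and colour channel the background normal distribution is
    estimated from the out-of-band measurements taken in that channel
    (the oob signal of probes declared in the *other* channel), and the
    in-band intensities are replaced by their posterior-mean true
    signal.  Dye equalisation then scales each channel so both channel
    means sit at their common mean.
    """
    if data.oob_meth is None or data.oob_unmeth is None:
        raise CapabilityError(
            "Noob requires out-of-band intensities (oob_meth/oob_unmeth)")
    ann = data.annotation
    is_t1 = ann.is_type("I")
    chan = ann.table["channel"].to_numpy()
    m_chan, u_chan = channel_of_signals(data)

    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    oob_m = data.oob_meth.to_numpy(dtype=float)
    oob_u = data.oob_unmeth.to_numpy(dtype=float)

    # oob of a Grn-declared Type I probe is read in Red, and vice versa
    bg_src = {"Grn": is_t1 & (chan == "Red"),
              "Red": is_t1 & (chan == "Grn")}
    n_samples = meth.shape[1]
    for j in range(n_samples):
        chan_means = {}
        for c in ("Grn", "Red"):
            src = bg_src[c]
            if not src.any():
                raise CapabilityError(
                    f"no Type I probes provide {c}-channel background")
            bg = np.concatenate([oob_m[src, j], oob_u[src, j]])
            bg = bg[np.isfinite(bg)]
            mu, sd = float(np.mean(bg)), float(np.std(bg, ddof=1))
            m_sel = m_chan == c
            u_sel = u_chan == c
            inband = np.concatenate([meth[m_sel, j], unmeth[u_sel, j]])
            alpha = float(np.mean(inband) - mu)
            meth[m_sel, j] = _normexp_signal(meth[m_sel, j], mu, sd, alpha)
            unmeth[u_sel, j] = _normexp_signal(unmeth[u_sel, j], mu, sd, alpha)
            chan_means[c] = float(np.mean(np.concatenate(
                [meth[m_sel, j], unmeth[u_sel, j]])))
        if dye_equalise:
            ref = 0.5 * (chan_means["Grn"] + chan_means["Red"])
            for c in ("Grn", "Red"):
                scale = ref / chan_means[c]
                meth[m_chan == c, j] *= scale
                unmeth[u_chan == c, j] *= scale

    idx, cols = data.meth.index, data.meth.columns
    return data.with_signal(pd.DataFrame(meth, index=idx, columns=cols),
                            pd.DataFrame(unmeth, index=idx, columns=cols))
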