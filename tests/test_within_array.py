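"""Within-array methods: SWAN, BMIQ, PBC, Noob.

The defining property — output for a sample is identical whether it is
normalised alone or inside any cohort — is asserted exactly, plus each
method's own distributional behaviour.
"""

import numpy as np
import pandas as pd
import pytest

from methnorm.core import BetaMatrix, IntensityData, beta_from_intensities
from methnorm.errors import CapabilityError
from methnorm.norm import bmiq_normalise, fit_beta_mixture, noob_normalise, \
    normalise, pbc_normalise, swan_normalise
from methnorm.simulate import BatchParams, SimulationConfig, simulate_study

from .conftest import make_annotation, make_samples


WITHIN = ["raw", "swan", "noob", "bmiq", "pbc"]


@pytest.mark.parametrize("method", WITHIN)
def test_sample_wise_invariance_exact(small_study, method):
    """Normalising one sample alone equals normalising it inside the
    cohort, bit for bit."""
    data = small_study.cohort_a
    first = data.samples.sample_ids[:3]
    alone = normalise(data.subset_samples(first), method)
    together = normalise(data, method)
    assert np.array_equal(alone.values.to_numpy(),
                          together.values.to_numpy()[:, :3])


@pytest.mark.parametrize("method", WITHIN + ["tost", "funnorm", "nasen",
                                             "dasen", "naten", "daten1",
                                             "daten2", "nanet", "danet",
                                             "nanes", "danes"])
def test_beta_output_in_unit_interval(small_study, method):
    betas = normalise(small_study.cohort_a.subset_samples(
        small_study.cohort_a.samples.sample_ids[:6]), method)
    x = betas.values.to_numpy()
    assert x.min() >= 0.0 and x.max() <= 1.0


@pytest.mark.parametrize("method", WITHIN)
def test_permutation_equivariance(small_study, method):
    data = small_study.cohort_a.subset_samples(
        small_study.cohort_a.samples.sample_ids[:6])
    perm = list(data.samples.sample_ids[::-1])
    out = normalise(data, method)
    out_perm = normalise(data.subset_samples(perm), method)
    assert np.array_equal(out.values[perm].to_numpy(),
                          out_perm.values.to_numpy())


class TestSwan:
    def test_matched_type_distributions_identity(self):
        """Equal Type I / Type II value multisets (single stratum) make
        the averaged subset distribution coincide with each type's own,
        so SWAN reduces to the identity."""
        from methnorm.core import ProbeAnnotation
        n = 200
        table = pd.DataFrame({
            "design_type": ["I"] * n + ["II"] * n,
            "channel": ["Grn"] * n + ["Both"] * n,
            "chromosome": "1", "special_class": "plain", "cpg_count": 2,
        }, index=pd.Index([f"cg{i:05d}" for i in range(2 * n)],
                          name="probe_id"))
        ann = ProbeAnnotation(table)
        samples = make_samples(2)
        rng = np.random.default_rng(0)
        block_m = rng.lognormal(8, 0.4, (n, 2))
        block_u = rng.lognormal(8, 0.4, (n, 2))
        meth = np.vstack([block_m, rng.permutation(block_m, axis=0)])
        unmeth = np.vstack([block_u, rng.permutation(block_u, axis=0)])
        df = lambda a: pd.DataFrame(a, index=ann.probe_ids,
                                    columns=samples.sample_ids)
        data = IntensityData(df(meth), df(unmeth), ann, samples)
        out = swan_normalise(data)
        raw = beta_from_intensities(data)
        assert np.abs(out.values.to_numpy()
                      - raw.values.to_numpy()).max() < 1e-9

    def test_subset_quantiles_agree_after(self, small_study):
        """Post-SWAN, within-sample quantiles of the two design types
        come together."""
        data = small_study.cohort_a.subset_samples(
            small_study.cohort_a.samples.sample_ids[:4])
        t1 = data.annotation.is_type("I")
        raw = beta_from_intensities(data).values.to_numpy()
        out = swan_normalise(data).values.to_numpy()
        qs = np.linspace(0.1, 0.9, 9)

        def gap(x):
            return np.abs(np.quantile(x[t1], qs, axis=0)
                          - np.quantile(x[~t1], qs, axis=0)).mean()

        assert gap(out) < gap(raw)


class TestBetaMixture:
    def test_recovers_planted_components(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.beta(5, 45, 400),     # mean 0.1
                            rng.beta(50, 50, 200),    # mean 0.5
                            rng.beta(45, 5, 400)])    # mean 0.9
        fit = fit_beta_mixture(x)
        assert np.allclose(fit["means"], [0.1, 0.5, 0.9], atol=0.05)
        assert np.allclose(fit["w"], [0.4, 0.2, 0.4], atol=0.05)

    def test_state_assignment_ordered(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.beta(5, 45, 300), rng.beta(45, 5, 300)])
        fit = fit_beta_mixture(x)
        assert set(fit["assign"][:300]) == {0}
        assert set(fit["assign"][300:]) == {2}


class TestBmiq:
    def _fixture(self, compress=0.6, seed=6):
        """Type II betas compressed toward 0.5 relative to Type I."""
        from methnorm.core import ProbeAnnotation
        n = 600
        table = pd.DataFrame({
            "design_type": ["I"] * n + ["II"] * n,
            "channel": ["Grn"] * n + ["Both"] * n,
            "chromosome": "1", "special_class": "plain", "cpg_count": 2,
        }, index=pd.Index([f"cg{i:05d}" for i in range(2 * n)],
                          name="probe_id"))
        ann = ProbeAnnotation(table)
        samples = make_samples(2)
        rng = np.random.default_rng(seed)
        b1 = np.concatenate([rng.beta(5, 45, n // 2), rng.beta(45, 5, n // 2)])
        b2 = 0.5 + compress * (np.concatenate(
            [rng.beta(5, 45, n // 2), rng.beta(45, 5, n // 2)]) - 0.5)
        vals = np.concatenate([b1, b2])
        values = pd.DataFrame(np.column_stack([vals, vals]),
                              index=ann.probe_ids,
                              columns=samples.sample_ids)
        return BetaMatrix(values, ann, samples), ann

    def test_identity_when_distributions_match(self):
        betas, ann = self._fixture(compress=1.0)
        out = bmiq_normalise(betas)
        assert np.abs(out.values.to_numpy()
                      - betas.values.to_numpy()).max() < 0.06

    def test_compressed_type2_pulled_to_type1_states(self):
        betas, ann = self._fixture(compress=0.6)
        out = bmiq_normalise(betas)
        t1 = ann.is_type("I")
        x = out.values.to_numpy()[:, 0]
        for lo, hi in ((0.0, 0.3), (0.7, 1.0)):
            med1 = np.median(x[t1][(x[t1] > lo) & (x[t1] < hi)])
            med2 = np.median(x[~t1][(x[~t1] > lo) & (x[~t1] < hi)])
            assert abs(med1 - med2) < 0.02

    def test_type1_untouched(self):
        betas, ann = self._fixture(compress=0.6)
        out = bmiq_normalise(betas)
        t1 = ann.is_type("I")
        clipped = np.clip(betas.values.to_numpy()[t1], 1e-6, 1 - 1e-6)
        assert np.allclose(out.values.to_numpy()[t1], clipped)


class TestPbc:
    def test_linear_compression_recovered(self):
        """Type II M-values at 0.8x the Type I pattern are rescaled by
        ~1/0.8 on each side."""
        from methnorm.core import ProbeAnnotation
        n = 500
        table = pd.DataFrame({
            "design_type": ["I"] * n + ["II"] * n,
            "channel": ["Grn"] * n + ["Both"] * n,
            "chromosome": "1", "special_class": "plain", "cpg_count": 2,
        }, index=pd.Index([f"cg{i:05d}" for i in range(2 * n)],
                          name="probe_id"))
        ann = ProbeAnnotation(table)
        samples = make_samples(1)
        rng = np.random.default_rng(7)
        m1 = np.concatenate([rng.normal(-3, 0.5, n // 2),
                             rng.normal(3, 0.5, n // 2)])
        m2 = 0.8 * rng.permutation(m1)
        m = np.concatenate([m1, m2])
        b = np.exp2(m) / (1 + np.exp2(m))
        betas = BetaMatrix(pd.DataFrame(b[:, None], index=ann.probe_ids,
                                        columns=samples.sample_ids),
                           ann, samples)
        out = pbc_normalise(betas)
        x = np.clip(out.values.to_numpy()[:, 0], 1e-6, 1 - 1e-6)
        m_out = np.log2(x / (1 - x))
        scale = m_out[n:] / m2
        assert np.abs(scale - 1 / 0.8).max() < 0.05 * (1 / 0.8)

    def test_matched_peaks_near_identity(self, small_study):
        data = small_study.cohort_a.subset_samples(
            small_study.cohort_a.samples.sample_ids[:2])
        betas = beta_from_intensities(data)
        ann = betas.annotation
        # feed Type II values into both types so peaks already agree
        t1 = ann.is_type("I")
        vals = betas.values.to_numpy().copy()
        vals[t1] = vals[~t1][:t1.sum()]
        same = BetaMatrix(pd.DataFrame(vals, index=betas.values.index,
                                       columns=betas.values.columns),
                          ann, betas.samples)
        out = pbc_normalise(same)
        assert np.abs(out.values.to_numpy() - np.clip(vals, 1e-6, 1 - 1e-6)
                      ).max() < 0.05


class TestNoob:
    def test_requires_oob(self, small_study):
        from dataclasses import replace
        data = replace(small_study.cohort_a, oob_meth=None, oob_unmeth=None)
        with pytest.raises(CapabilityError):
            noob_normalise(data)

    def test_output_strictly_positive(self, small_study):
        out = noob_normalise(small_study.cohort_a.subset_samples(
            small_study.cohort_a.samples.sample_ids[:4]))
        assert out.meth.to_numpy().min() > 0.0
        assert out.unmeth.to_numpy().min() > 0.0

    def test_near_zero_background_preserves_signal(self):
        """With a tiny simulated background the corrected intensities
        track the raw signal."""
        cfg = SimulationConfig(
            n_plain=600, n_dmr=10, n_snp=10, n_x=20, n_samples=6,
            batch_a=BatchParams(background_type1=5.0, background_type2=5.0),
            batch_b=BatchParams(background_type1=5.0, background_type2=5.0),
            noise_sd=2.0, seed=17)
        st = simulate_study(cfg)
        data = st.cohort_a
        out = noob_normalise(data, dye_equalise=False)
        raw = data.meth.to_numpy()
        corrected = out.meth.to_numpy()
        rel = np.abs(corrected - raw) / np.maximum(raw, 50)
        assert np.median(rel) < 0.05
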