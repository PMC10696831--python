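"""Separate-vs-joint robustness statistics and the benchmark loop."""

import numpy as np
import pandas as pd
import pytest

from methnorm.core import SampleSheet
from methnorm.episcore import EpiScoreModel
from methnorm.errors import ValidationError
from methnorm.robustness import (PairedScores, full_benchmark,
                                 incremental_r2, median_abs_diff,
                                 pearson_with_ci, percentile_shift,
                                 separate_vs_joint)

from .conftest import make_samples


def _model_from_truth(study, n=30):
    w = study.truth_a.causal_weights.iloc[:n]
    return EpiScoreModel(intercept=0.0, weights=w,
                         feature_means=pd.Series(0.0, index=w.index))


def _paired(sep, joint, pheno=None):
    sep = np.asarray(sep, dtype=float)
    table = pd.DataFrame({
        "cohort": "C",
        "score_separate": sep,
        "score_joint": np.asarray(joint, dtype=float),
    }, index=pd.Index([f"s{i}" for i in range(len(sep))], name="sample_id"))
    from scipy.stats import rankdata
    for arm in ("separate", "joint"):
        x = table[f"score_{arm}"].to_numpy()
        table[f"percentile_{arm}"] = 100 * (rankdata(x) - 0.5) / len(x)
    if pheno is not None:
        table["phenotype"] = pheno
    return PairedScores(table)


class TestSeparateVsJoint:
    def test_raw_arms_identical(self, small_study):
        st = small_study
        model = _model_from_truth(st)
        paired = separate_vs_joint(st.cohort_a, st.cohort_b, "raw", model)
        assert median_abs_diff(paired) == 0.0
        t = paired.table
        assert np.array_equal(t["score_separate"], t["score_joint"])

    @pytest.mark.parametrize("method", ["swan", "pbc"])
    def test_within_array_arms_identical(self, small_study, method):
        st = small_study
        model = _model_from_truth(st)
        paired = separate_vs_joint(st.cohort_a, st.cohort_b, method, model)
        diff = np.abs(paired.table["score_separate"]
                      - paired.table["score_joint"])
        assert diff.max() <= 1e-12

    def test_between_array_moves_scores(self, small_study):
        st = small_study
        model = _model_from_truth(st)
        paired = separate_vs_joint(st.cohort_a, st.cohort_b, "nasen", model)
        assert median_abs_diff(paired) > 0.0


class TestMedianAbsDiff:
    def test_identical_arms_zero(self):
        assert median_abs_diff(_paired([1, 2, 3], [1, 2, 3])) == 0.0

    def test_manual_median(self):
        p = _paired([0.1, -0.3, 0.2], [0.0, 0.0, 0.0])
        assert median_abs_diff(p) == 0.2

    def test_translation_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert np.isclose(median_abs_diff(_paired(a, b)),
                          median_abs_diff(_paired(a + 5, b + 5)))

    def test_even_count_median(self):
        p = _paired([0.0, 0.0], [0.1, 0.3])
        assert median_abs_diff(p) == pytest.approx(0.2)


class TestPearsonCI:
    def test_perfect_correlation(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        r, lo, hi = pearson_with_ci(s, s * 2 + 1)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        sx = pd.Series(x, index=[f"s{i}" for i in range(50)])
        sy = pd.Series(y, index=sx.index)
        r, lo, hi = pearson_with_ci(sx, sy)
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(manual, abs=1e-12)
        assert lo < r < hi

    def test_ci_narrows_with_n(self):
        rng = np.random.default_rng(2)
        idx_small = [f"s{i}" for i in range(50)]
        idx_big = [f"s{i}" for i in range(500)]
        x1 = pd.Series(rng.normal(size=50), index=idx_small)
        y1 = pd.Series(0.5 * x1.to_numpy() + rng.normal(size=50),
                       index=idx_small)
        x2 = pd.Series(rng.normal(size=500), index=idx_big)
        y2 = pd.Series(0.5 * x2.to_numpy() + rng.normal(size=500),
                       index=idx_big)
        _, lo1, hi1 = pearson_with_ci(x1, y1)
        _, lo2, hi2 = pearson_with_ci(x2, y2)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_zero_variance_rejected(self):
        s = pd.Series([1.0] * 10, index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            pearson_with_ci(s, s)


class TestIncrementalR2:
    def _setup(self, n=200, seed=3):
        # score RNG must be independent of the sample-sheet RNG: the
        # same seed would reproduce the age column's normal draws and
        # make the design exactly collinear
        rng = np.random.default_rng(seed + 1000)
        samples = make_samples(n, seed=seed)
        bmi = samples.table["bmi"]
        return samples, bmi, rng

    def test_orthogonal_score_adds_nothing(self):
        samples, bmi, rng = self._setup()
        score = pd.Series(rng.normal(size=len(bmi)), index=bmi.index)
        val = incremental_r2(bmi, samples, score)
        assert abs(val) < 3.0

    def test_exact_null_residual_identity(self):
        """A score equal to the null-model residual realises the whole
        remaining variance: incremental R^2 = 100 * (1 - R^2_null)."""
        samples, bmi, _ = self._setup()
        y = np.log(bmi.to_numpy())
        male = (samples.table["sex"] == "M").to_numpy(float)
        X = np.column_stack([np.ones(len(y)),
                             samples.table["age"].to_numpy(), male])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ coef
        r2_null = 1 - np.sum(resid ** 2) / np.sum((y - y.mean()) ** 2)
        score = pd.Series(resid, index=bmi.index)
        val = incremental_r2(bmi, samples, score)
        assert val == pytest.approx(100 * (1 - r2_null), abs=1e-6)

    def test_never_negative(self):
        samples, bmi, rng = self._setup(seed=4)
        for k in range(3):
            score = pd.Series(rng.normal(size=len(bmi)), index=bmi.index)
            assert incremental_r2(bmi, samples, score) >= -1e-9


class TestPercentileShift:
    def test_identical_arms(self):
        res = percentile_shift(_paired([1, 2, 3, 4], [1, 2, 3, 4]))
        assert res["max_shift"] == 0.0 and res["spearman"] == 1.0

    def test_swapped_neighbours_shift(self):
        sep = list(range(10))
        joint = sep.copy()
        joint[3], joint[4] = joint[4], joint[3]
        res = percentile_shift(_paired(sep, joint))
        assert res["max_shift"] == pytest.approx(10.0)

    def test_monotone_transform_preserves_spearman(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        r1 = percentile_shift(_paired(a, b))["spearman"]
        r2 = percentile_shift(_paired(a, np.exp(b)))["spearman"]
        assert r1 == pytest.approx(r2)


BENCH_METHODS = ["raw", "swan", "pbc", "nasen", "nanet"]


@pytest.fixture(scope="module")
def result(small_study):
    model = _model_from_truth(small_study)
    return full_benchmark(small_study.cohort_a, small_study.cohort_b,
                          BENCH_METHODS, model)


class TestFullBenchmark:
    METHODS = BENCH_METHODS

    def test_row_per_method(self, result):
        assert list(result.summary.index) == self.METHODS
        assert not result.failures

    def test_within_array_mad_zero(self, result):
        for m in ("raw", "swan", "pbc"):
            assert result.summary.loc[m, "mad"] <= 1e-12

    def test_metrics_and_ranks_present(self, result):
        for col in ("dmrse_target", "gcose_joint", "seabird_reference",
                    "mean_rank", "r_separate", "incremental_r2"):
            assert col in result.summary.columns
        assert result.summary["mean_rank"].notna().all()

    def test_deterministic_repeat(self, small_study):
        model = _model_from_truth(small_study)
        r1 = full_benchmark(small_study.cohort_a, small_study.cohort_b,
                            ["raw", "nasen"], model)
        r2 = full_benchmark(small_study.cohort_a, small_study.cohort_b,
                            ["raw", "nasen"], model)
        assert r1.summary.equals(r2.summary)

    def test_fail_soft_records_failure(self, small_study):
        from dataclasses import replace
        model = _model_from_truth(small_study)
        no_oob_a = replace(small_study.cohort_a, oob_meth=None,
                           oob_unmeth=None)
        no_oob_b = replace(small_study.cohort_b, oob_meth=None,
                           oob_unmeth=None)
        res = full_benchmark(no_oob_a, no_oob_b, ["raw", "noob"], model,
                             compute_metrics=False)
        assert "noob" in res.failures
        assert list(res.summary.index) == ["raw"]

    def test_mad_invariant_to_reference_order(self, small_study):
        st = small_study
        model = _model_from_truth(st)
        ref = st.cohort_b
        flipped = ref.subset_samples(list(ref.samples.sample_ids[::-1]))
        p1 = separate_vs_joint(st.cohort_a, ref, "nasen", model)
        p2 = separate_vs_joint(st.cohort_a, flipped, "nasen", model)
        assert np.isclose(median_abs_diff(p1), median_abs_diff(p2),
                          atol=1e-12)

    def test_self_join_mad_zero(self, small_study):
        """Joining a cohort with a relabelled copy of itself leaves
        every method's scores unchanged (up to float accumulation)."""
        st = small_study
        target = st.cohort_a.subset_samples(
            st.cohort_a.samples.sample_ids[:20])
        clone_sheet = target.samples.table.copy()
        clone_sheet.index = pd.Index([f"X{i}" for i in range(len(clone_sheet))],
                                     name="sample_id")
        rename = dict(zip(target.samples.sample_ids, clone_sheet.index))
        from dataclasses import replace
        kw = {}
        for name in ("meth", "unmeth", "oob_meth", "oob_unmeth",
                     "beadcount", "detection_p"):
            mat = getattr(target, name)
            kw[name] = None if mat is None else mat.rename(columns=rename)
        clone = replace(target, samples=SampleSheet(clone_sheet), **kw)
        model = _model_from_truth(st)
        for method in ("nasen", "naten", "funnorm"):
            paired = separate_vs_joint(target, clone, method, model)
            assert median_abs_diff(paired) < 1e-9, method
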