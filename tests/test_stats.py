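"""Agreement statistics: Friedman/Kendall-w, post-hoc, ICC, TOST, Bland-Altman."""

import numpy as np
import pytest
from scipy import stats as sps

from hreflex import (
    RepeatedMeasures,
    bland_altman,
    friedman_test,
    icc_absolute_single,
    kendalls_w,
    kendalls_w_label,
    tost_equivalence,
    tukey_posthoc,
)


class TestFriedman:
    def test_identical_columns_null(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = friedman_test(x)
        assert res.chi2_uncorrected == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_perfect_concordance_reaches_maximum(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.standard_normal((8, 4)), axis=1)
        res = friedman_test(x)
        n, k = x.shape
        assert res.chi2_uncorrected == pytest.approx(n * (k - 1))
        assert res.w == pytest.approx(1.0)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((12, 4))
        res = friedman_test(x)
        chi2_ref, p_ref = sps.friedmanchisquare(*x.T)
        assert res.chi2 == pytest.approx(chi2_ref)
        assert res.p == pytest.approx(p_ref)

    def test_chi2_p_close_to_exact_null_on_5x3(self):
        """The chi-square reference tracks the exact permutation null at N=5
        to within the coarseness of the approximation."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal((5, 3))
        approx = friedman_test(x).p
        exact = friedman_test(x, exact=True).p
        assert approx == pytest.approx(exact, abs=0.05)

    def test_exact_p_of_perfect_concordance_is_closed_form(self):
        # only the 3! fully concordant assignments reach the maximal statistic,
        # so p = 3! / (3!)^5
        x = np.sort(np.random.default_rng(0).standard_normal((5, 3)), axis=1)
        res = friedman_test(x, exact=True)
        assert res.p == pytest.approx(6 / 6**5, rel=1e-12)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((5, 1)))

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 3))
        perm = rng.permutation(10)
        assert friedman_test(x).chi2 == pytest.approx(friedman_test(x[perm]).chi2)

    def test_type_one_error_calibrated(self):
        """On null cohorts the test rejects at ~alpha (chi-square reference is
        slightly conservative at k=3)."""
        rng = np.random.default_rng(2024)
        rejections = sum(
            friedman_test(rng.standard_normal((21, 3))).p < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rejections / 2000 <= 0.07


class TestKendallsW:
    def test_zero_chi2_gives_zero(self):
        assert kendalls_w(0.0, 21, 3) == 0.0

    def test_bounded_in_unit_interval_from_uncorrected_chi2(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            res = friedman_test(rng.standard_normal((6, 4)))
            assert 0.0 <= res.w <= 1.0

    def test_labels_follow_interpretation_bands(self):
        assert kendalls_w_label(0.05) == "negligible"
        assert kendalls_w_label(0.2) == "small"
        assert kendalls_w_label(0.4) == "moderate"
        assert kendalls_w_label(0.8) == "large"

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kendalls_w(5.0, 21, 1)


class TestTukeyPosthoc:
    def test_identical_columns_all_p_one(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        for _, _, p in tukey_posthoc(x):
            assert p == pytest.approx(1.0, abs=1e-6)

    def test_extreme_pair_has_smallest_p(self):
        rng = np.random.default_rng(9)
        n = 20
        x = np.column_stack([
            rng.normal(0.0, 1.0, n),
            rng.normal(1.5, 1.0, n),
            rng.normal(6.0, 1.0, n),
        ])
        pairs = {(a, b): p for a, b, p in tukey_posthoc(x)}
        assert pairs[(0, 2)] == min(pairs.values())

    def test_two_conditions_reduce_to_friedman(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((15, 2))
        (_, _, p_tukey), = tukey_posthoc(x)
        assert p_tukey == pytest.approx(friedman_test(x).p, abs=0.01)

    def test_symmetric_in_the_pair(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 3))
        res = {frozenset((a, b)): p for a, b, p in tukey_posthoc(x)}
        assert len(res) == 3


class TestIcc:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 3.0, 5.0, 9.0, 12.0, 20.0])
        res = icc_absolute_single(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0)
        assert res.label == "excellent"

    def test_absolute_agreement_penalizes_offsets(self):
        col = np.array([1.0, 3.0, 5.0, 9.0, 12.0, 20.0])
        shifted = np.column_stack([col, col + 15.0])
        res = icc_absolute_single(shifted)
        # consistency-type ICC would still be 1; absolute agreement must drop
        assert res.icc < 0.5

    def test_matches_hand_computed_anova_on_6x2_table(self):
        x = np.array([
            [10.0, 12.0],
            [12.0, 15.0],
            [18.0, 20.0],
            [8.0, 9.0],
            [22.0, 21.0],
            [15.0, 18.0],
        ])
        # independent oracle: explicit two-way ANOVA mean squares
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((x - grand) ** 2).sum() - (n - 1) / k * msr * k - (k - 1) / n * msc * n
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert icc_absolute_single(x).icc == pytest.approx(expected, rel=1e-10)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(21)
        x = rng.normal(10.0, 3.0, (12, 2)) + rng.normal(0, 1, (12, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        row = ref[ref.Type == "ICC(A,1)"]
        res = icc_absolute_single(x)
        assert res.icc == pytest.approx(row["ICC"].item(), abs=1e-6)
        ci = row["CI95"].item()
        assert res.ci[0] == pytest.approx(ci[0], abs=0.02)
        assert res.ci[1] == pytest.approx(ci[1], abs=0.02)

    def test_zero_variance_flagged_undefined(self):
        res = icc_absolute_single(np.full((5, 2), 3.0))
        assert not res.defined


class TestTost:
    def test_all_zero_differences_equivalent(self):
        res = tost_equivalence(np.zeros(8), bounds=1.0)
        assert res.ci90 == (0.0, 0.0)
        assert res.equivalent

    def test_wide_dispersion_not_equivalent(self):
        # mean 0, sd 10, N=5: CI halfwidth = t(0.95, 4) * 10 / sqrt(5) >> 1
        d = np.array([-10.0, -5.0, 0.0, 5.0, 10.0]) * (10.0 / 7.905694150420948)
        res = tost_equivalence(d, bounds=1.0)
        half = sps.t.ppf(0.95, 4) * np.std(d, ddof=1) / np.sqrt(5)
        assert res.ci90[1] == pytest.approx(half)
        assert not res.equivalent

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0, 0.2, 10)
        base = tost_equivalence(d)
        shifted = tost_equivalence(d + 0.5)
        assert shifted.ci90[0] == pytest.approx(base.ci90[0] + 0.5)
        assert shifted.ci90[1] == pytest.approx(base.ci90[1] + 0.5)


class TestBlandAltman:
    def test_identical_pairs(self):
        col = np.arange(5.0)
        bias, lo, hi = bland_altman(np.column_stack([col, col]))
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_known_two_point_differences(self):
        pairs = np.array([[1.0, 2.0], [2.0, 1.0]])  # differences -1, +1
        bias, lo, hi = bland_altman(pairs)
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2.0))
        assert lo == pytest.approx(-hi)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(17)
        pairs = rng.normal(5, 1, (20, 2))
        bias, lo, hi = bland_altman(pairs)
        assert hi - bias == pytest.approx(bias - lo)


class TestRepeatedMeasures:
    def test_listwise_deletion_counts_dropped(self):
        import pandas as pd

        df = pd.DataFrame({
            "subject": ["a", "a", "b", "b", "c"],
            "cond": [1, 2, 1, 2, 1],
            "y": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        rm = RepeatedMeasures.from_table(df, value="y", subject="subject",
                                         condition="cond")
        assert rm.values.shape == (2, 2)
        assert rm.n_dropped == 1
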