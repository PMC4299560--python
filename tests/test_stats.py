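import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ctild.errors import (
    DegenerateICCError,
    UndefinedCorrelationError,
    ValidationError,
)
from ctild.stats import (
    clopper_pearson,
    compare_groups,
    criterion_table,
    hanley_mcneil_se,
    icc_two_way,
    pearson_regression,
    roc_analysis,
)


def mann_whitney_auc(scores, labels):
    """Exhaustive pair-counting oracle with ties counted 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestPearsonRegression:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_regression(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_regression(x, -x).r == pytest.approx(-1.0)

    def test_hand_evaluated_r(self):
        # sum formulas by hand: covariance 3, variances 5 and 5 -> r = 0.6
        res = pearson_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = pearson_regression(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        p = 2 * sps.t.sf(abs(t), res.n - 2)
        assert res.p_value == pytest.approx(p)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_raises(self):
        with pytest.raises(ValidationError):
            pearson_regression([1.0, 2.0], [1.0, 2.0])


def anova_icc_oracle(m):
    """Independent mean-squares oracle for ICC(2,1) built from first
    principles on a small matrix."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    msr = k * sum((row.mean() - grand) ** 2 for row in m) / (n - 1)
    msc = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_one(self):
        m = np.c_[[1.0, 5.0, 9.0, 3.0], [1.0, 5.0, 9.0, 3.0]]
        assert icc_two_way(m) == pytest.approx(1.0)

    def test_toy_matrix_matches_anova_oracle(self):
        m = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0]])
        assert icc_two_way(m) == pytest.approx(anova_icc_oracle(m))

    def test_constant_shift_agreement_below_consistency(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 10, size=40)
        m = np.c_[base, base + 2.0]
        agreement = icc_two_way(m, form="agreement")
        consistency = icc_two_way(m, form="consistency")
        assert consistency == pytest.approx(1.0)
        assert agreement < consistency
        assert agreement > 0.9  # between-subject variance >> shift^2

    def test_matches_pingouin_both_forms(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1)) * 2
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "rater": list(range(3)) * 15,
                "score": m.ravel(),
            }
        )
        t = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc_two_way(m) == pytest.approx(float(t.loc["ICC(A,1)", "ICC"]))
        assert icc_two_way(m, form="consistency") == pytest.approx(
            float(t.loc["ICC(C,1)", "ICC"])
        )

    def test_known_variance_components_recovered(self):
        # subjects ~ N(0, 16), rater noise ~ N(0, 4): ICC = 16/20 = 0.8
        rng = np.random.default_rng(11)
        subjects = rng.normal(0, 4, size=(5000, 1))
        m = subjects + rng.normal(0, 2, size=(5000, 2))
        assert icc_two_way(m) == pytest.approx(0.8, abs=0.02)

    def test_degenerate_matrix_raises(self):
        with pytest.raises(DegenerateICCError):
            icc_two_way(np.full((5, 2), 3.0))

    def test_bad_shape_rejected(self):
        with pytest.raises(ValidationError):
            icc_two_way(np.array([[1.0], [2.0]]))


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        t, _ = compare_groups([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_chi_square_independence(self):
        chi2, p = compare_groups((10, 10), (10, 10), kind="chi_square")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi_square_matches_scipy(self):
        chi2, p = compare_groups((20, 10), (5, 25), kind="chi_square")
        expected = sps.chi2_contingency([[20, 10], [5, 25]], correction=False)
        assert chi2 == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([2.0, 2.0], [2.0, 2.0])


class TestROC:
    def test_perfectly_separated(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        idx = np.where(roc.thresholds == roc.optimal_threshold)[0][0]
        assert roc.sensitivities[idx] == 1.0
        assert roc.specificities[idx] == 1.0

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.04)

    def test_trapezoid_equals_mann_whitney_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(8, 50))
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="classes"):
            roc_analysis([1.0, 2.0], [True, True])

    def test_monotone_staircase(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        roc = roc_analysis(scores, labels)
        assert (np.diff(roc.sensitivities) <= 1e-12).all()
        assert (np.diff(roc.specificities) >= -1e-12).all()

    def test_auc_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(np.exp(scores), labels).auc
        assert a == pytest.approx(b)

    def test_auc_symmetry(self):
        rng = np.random.default_rng(19)
        scores = rng.integers(0, 5, size=120).astype(float)
        labels = rng.random(120) < 0.5
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_youden_tie_breaking_smallest_threshold(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 1, 1], dtype=bool)
        roc = roc_analysis(scores, labels)
        # criteria 1.0 and 2.0 both give sens+spec=2; smallest wins
        assert roc.optimal_threshold == 1.0

    def test_hanley_mcneil_formula(self):
        auc, n_pos, n_neg = 0.886, 41, 39
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        expected = np.sqrt(
            (auc * (1 - auc) + 40 * (q1 - auc**2) + 38 * (q2 - auc**2)) / (41 * 39)
        )
        assert hanley_mcneil_se(auc, n_pos, n_neg) == pytest.approx(expected)

    @given(st.integers(min_value=0, max_value=4000))
    @settings(max_examples=30, deadline=None)
    def test_auc_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        roc = roc_analysis(scores, labels)
        assert 0.0 <= roc.auc <= 1.0


class TestCriterionTable:
    @staticmethod
    def build_roc(tp, fn, tn, fp, criterion=20.0):
        """Scores/labels engineered to hit the given confusion at the
        criterion."""
        pos = np.concatenate([np.full(tp, criterion + 5.0), np.full(fn, criterion - 5.0)])
        neg = np.concatenate([np.full(fp, criterion + 5.0), np.full(tn, criterion - 5.0)])
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(tp + fn, bool), np.zeros(fp + tn, bool)])
        return roc_analysis(scores, labels)

    def test_direct_division_sens_spec(self):
        roc = self.build_roc(tp=31, fn=10, tn=38, fp=1)
        rows = criterion_table(roc)
        row = next(r for r in rows if r.criterion == 15.0)  # the low plateau value
        assert row.sensitivity_pct == pytest.approx(100 * 31 / 41, abs=1e-9)
        assert row.specificity_pct == pytest.approx(100 * 38 / 39, abs=1e-9)
        assert row.lr_pos == pytest.approx((31 / 41) / (1 / 39))
        assert row.lr_neg == pytest.approx((10 / 41) / (38 / 39))

    def test_perfect_criterion_row(self):
        roc = self.build_roc(tp=10, fn=0, tn=10, fp=0)
        rows = criterion_table(roc)
        row = next(r for r in rows if r.sensitivity_pct == 100.0 and r.specificity_pct == 100.0)
        assert row.lr_pos is None  # specificity 100% -> +LR omitted
        assert row.lr_neg == 0.0
        assert row.ppv_pct == 100.0
        assert row.npv_pct == 100.0

    def test_clopper_pearson_zero_successes_matches_beta_oracle(self):
        low, high = clopper_pearson(0, 39)
        assert low == 0.0
        assert high == pytest.approx(float(sps.beta.ppf(0.975, 1, 39)))
        # closed form for x=0: 1 - (alpha/2)^(1/n)
        assert high == pytest.approx(1 - 0.025 ** (1 / 39))

    def test_clopper_pearson_full_successes(self):
        low, high = clopper_pearson(39, 39)
        assert high == 1.0
        assert low == pytest.approx(float(sps.beta.ppf(0.025, 39, 1)))

    def test_clopper_pearson_interior_matches_beta(self):
        low, high = clopper_pearson(31, 41)
        assert low == pytest.approx(float(sps.beta.ppf(0.025, 31, 11)))
        assert high == pytest.approx(float(sps.beta.ppf(0.975, 32, 10)))

    def test_ci_brackets_point_estimate(self):
        roc = self.build_roc(tp=31, fn=10, tn=38, fp=1)
        for row in criterion_table(roc):
            lo, hi = row.sensitivity_ci
            assert lo - 1e-9 <= row.sensitivity_pct <= hi + 1e-9
            lo, hi = row.specificity_ci
            assert lo - 1e-9 <= row.specificity_pct <= hi + 1e-9

    def test_sensitivity_non_increasing_with_criterion(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=150)
        labels = rng.random(150) < 0.5
        rows = criterion_table(roc_analysis(scores, labels))
        sens = [r.sensitivity_pct for r in rows]
        assert all(a >= b - 1e-9 for a, b in zip(sens, sens[1:]))
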