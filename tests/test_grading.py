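"""LOCS III grade handling and the grading-evaluation battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from myocat.grading import (
    CataractSubtype,
    LocsGrade,
    auc_confidence_interval,
    binary_metrics,
    delong_compare,
    grading_error,
    icc_absolute,
    re_1_0,
    roc_auc,
    surgical_indication,
)


def nuc(v):
    return LocsGrade(CataractSubtype.NUCLEAR, v)


def cort(v):
    return LocsGrade(CataractSubtype.CORTICAL, v)


class TestGradesAndErrors:
    @pytest.mark.parametrize("sub, lo, hi", [("nuclear", 1.0, 6.0), ("cortical", 1.0, 5.0), ("psc", 1.0, 5.0)])
    def test_grade_range_enforced(self, sub, lo, hi):
        LocsGrade(sub, lo)
        LocsGrade(sub, hi)
        with pytest.raises(ValueError):
            LocsGrade(sub, hi + 0.1)
        with pytest.raises(ValueError):
            LocsGrade(sub, lo - 0.1)

    @pytest.mark.parametrize(
        "a, b, expected",
        [((4.0, 3.0), None, 1.0), ((2.5, 2.5), "cortical", 0.0), ((1.0, 6.0), None, 5.0)],
    )
    def test_grading_error_values(self, a, b, expected):
        make = cort if b == "cortical" else nuc
        assert grading_error(make(a[0]), make(a[1])) == pytest.approx(expected)

    def test_grading_error_subtype_mismatch(self):
        with pytest.raises(ValueError):
            grading_error(nuc(3.0), cort(3.0))


class TestRe10:
    def test_published_internal_fraction(self):
        errors = [0.0] * 106 + [1.5]
        assert re_1_0(errors) == pytest.approx(100 * 106 / 107)
        assert round(re_1_0(errors), 2) == 99.07

    def test_boundary_counts_as_within(self):
        assert re_1_0([0.5, 1.0, 1.1, 2.0]) == 50.0

    def test_all_zero_and_empty(self):
        assert re_1_0([0.0, 0.0]) == 100.0
        with pytest.raises(ValueError):
            re_1_0([])

    def test_permutation_invariant(self):
        errors = [0.2, 1.4, 0.9, 3.0, 1.0]
        assert re_1_0(errors) == re_1_0(errors[::-1])


class TestSurgicalIndication:
    @pytest.mark.parametrize(
        "n, c, expected",
        [(4.0, 2.0, True), (3.5, 3.5, False), (1.0, 5.0, True), (3.6, 1.0, True), (2.0, 2.0, False)],
    )
    def test_threshold_rule_strict(self, n, c, expected):
        assert surgical_indication(nuc(n), cort(c)) is expected

    @given(st.floats(1.0, 6.0), st.floats(1.0, 5.0), st.floats(1.0, 6.0), st.floats(1.0, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_grade(self, n1, c1, n2, c2):
        lo = surgical_indication(min(n1, n2), min(c1, c2))
        hi = surgical_indication(max(n1, n2), max(c1, c2))
        assert hi >= lo


class TestBinaryMetrics:
    def test_perfect_prediction(self):
        bm = binary_metrics([True, False, True], [True, False, True])
        assert (bm.accuracy, bm.sensitivity, bm.specificity) == (1.0, 1.0, 1.0)

    def test_all_positive_prediction(self):
        bm = binary_metrics([True] * 4, [True, True, False, False])
        assert bm.sensitivity == 1.0 and bm.specificity == 0.0 and bm.accuracy == 0.5

    def test_mixed_hand_2x2(self):
        bm = binary_metrics([True, False, True, False], [True, True, False, False])
        assert bm.accuracy == 0.5 and bm.sensitivity == 0.5 and bm.specificity == 0.5

    def test_undefined_margins_are_none(self):
        assert binary_metrics([True, True], [True, True]).specificity is None
        assert binary_metrics([False, False], [False, False]).sensitivity is None


class TestICC:
    def test_identical_raters_give_one(self):
        pairs = [(1.0, 1.0), (2.0, 2.0), (3.5, 3.5), (5.0, 5.0)]
        assert icc_absolute(pairs).value == pytest.approx(1.0)

    def test_constant_offset_penalised(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        shifted = [(x, x + 10.0) for x in base]
        assert icc_absolute(shifted).value < 0.2

    def test_six_pair_worked_set_matches_anova_oracle(self):
        pairs = [(2.0, 2.5), (3.1, 3.0), (4.2, 4.8), (1.5, 1.0), (5.0, 4.6), (3.3, 3.9)]
        # independent brute-force two-way ANOVA decomposition
        data = np.array(pairs)
        n, k = data.shape
        grand = data.mean()
        msr = k * sum((data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
        msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
        sse = sum(
            (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
            for i in range(n)
            for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_absolute(pairs).value == pytest.approx(expected, abs=1e-9)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        a = rng.uniform(1, 6, size=20)
        b = a + rng.normal(0, 0.5, size=20)
        ours = icc_absolute(list(zip(a, b))).value
        df = pd.DataFrame(
            {
                "target": np.repeat(np.arange(20), 2),
                "rater": np.tile(["a", "b"], 20),
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="target", raters="rater", ratings="score")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].item()  # ICC(2,1)
        assert ours == pytest.approx(icc2, abs=1e-9)

    def test_rater_exchange_invariance(self):
        pairs = [(1.0, 2.0), (3.0, 2.5), (4.0, 4.4), (2.2, 2.0)]
        swapped = [(b, a) for a, b in pairs]
        assert icc_absolute(pairs).value == pytest.approx(icc_absolute(swapped).value)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            icc_absolute([(1.0, 1.0), (2.0, 2.0)])
        assert icc_absolute([(2.0, 2.0)] * 5).value is None


def _exhaustive_auc(scores, labels):
    """Oracle: concordance fraction over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [False, False, True, True]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 1, 1, 1], [False, True, False, True]).auc == 0.5

    def test_single_swap_hand_value(self):
        assert roc_auc([1, 3, 2, 4], [False, False, True, True]).auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=50).filter(lambda s: len(set(s)) > 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_pairwise_oracle(self, scores):
        labels = [i % 2 == 0 for i in range(len(scores))]
        result = roc_auc(scores, labels)
        assert result.auc == pytest.approx(_exhaustive_auc(scores, labels), abs=1e-12)
        assert result.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestDelong:
    def test_identical_scores_no_difference(self):
        s = [0.2, 0.8, 0.4, 0.9, 0.1, 0.7]
        y = [False, True, False, True, False, True]
        res = delong_compare(s, s, y)
        assert res.auc_a == res.auc_b
        assert res.p_value == 1.0

    def test_auc_agrees_with_roc_auc_exactly(self):
        rng = np.random.default_rng(2)
        y = rng.random(30) < 0.5
        y[0], y[1] = True, False
        a, b = rng.random(30), rng.random(30)
        res = delong_compare(a, b, y)
        assert res.auc_a == pytest.approx(roc_auc(a, y).auc, abs=1e-15)
        assert res.auc_b == pytest.approx(roc_auc(b, y).auc, abs=1e-15)

    def test_variance_against_resampling_oracles(self):
        # n=8 hand case.  The grouped (two-sample) delete-one jackknife is
        # algebraically identical to the structural-components estimator,
        # so it must match to numerical precision; the stratified bootstrap
        # (100k resamples, fixed seed) is only a loose plausibility check
        # at this sample size.
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.2, 0.9, 0.65, 0.7])
        labels = np.array([False, False, False, False, True, True, True, True])
        res = delong_compare(scores, scores, labels)

        jack_var = 0.0
        for cls in (True, False):
            idx = np.where(labels == cls)[0]
            g = len(idx)
            thetas = []
            for i in idx:
                keep = np.ones(len(scores), bool)
                keep[i] = False
                thetas.append(roc_auc(scores[keep], labels[keep]).auc)
            thetas = np.array(thetas)
            jack_var += (g - 1) / g * ((thetas - thetas.mean()) ** 2).sum()
        assert res.var_a == pytest.approx(jack_var, rel=1e-9)

        rng = np.random.default_rng(99)
        pos, neg = scores[labels], scores[~labels]
        B = 100_000
        pi = rng.integers(0, 4, size=(B, 4))
        ni = rng.integers(0, 4, size=(B, 4))
        diff = pos[pi][:, :, None] - neg[ni][:, None, :]
        aucs = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0)).mean(axis=(1, 2))
        assert res.var_a == pytest.approx(aucs.var(ddof=1), rel=0.35)

    def test_detects_clear_difference(self):
        rng = np.random.default_rng(3)
        y = np.repeat([True, False], 60)
        good = np.where(y, 1.0, 0.0) + rng.normal(0, 0.3, 120)
        bad = rng.normal(0, 1, 120)
        res = delong_compare(good, bad, y)
        assert res.p_value < 0.01
        assert res.auc_a > res.auc_b

    def test_single_auc_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        y = rng.random(40) < 0.5
        y[:2] = [True, False]
        s = rng.random(40) + 0.5 * y
        auc, (lo, hi) = auc_confidence_interval(s, y)
        assert 0.0 <= lo <= auc <= hi <= 1.0
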