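"""ROC/AUC, Youden cut-offs, confusion metrics, grading, group comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swaysense import (
    ConfusionCounts,
    DataError,
    DegenerateCohortError,
    FallCriterion,
    SubjectRecord,
    ValidationError,
    auc,
    auc_se_ci,
    confusion,
    grade,
    group_compare,
    label_faller,
    metrics,
    roc_curve,
    summarize_roc,
    youden_cutoff,
)
from swaysense.diagnostics import RocSummary


def pair_counting_auc(scores, labels):
    """Brute-force Mann–Whitney probability: P(pos > neg) + P(tie)/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def random_cohort(seed, max_n=12, tie_prone=True):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_n + 1))
    scores = (
        rng.integers(0, 5, n).astype(float) if tie_prone else rng.normal(size=n)
    )
    labels = rng.integers(0, 2, n).astype(bool)
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return scores, labels


class TestLabeling:
    def mk(self, **kw):
        defaults = dict(subject_id="s", group="MCI")
        defaults.update(kw)
        return SubjectRecord(**defaults)

    @pytest.mark.parametrize(
        "kwargs, criterion, expected",
        [
            (dict(bbs_score=39), FallCriterion(mode="bbs"), True),
            (dict(bbs_score=40), FallCriterion(mode="bbs"), False),
            (dict(bbs_score=40), FallCriterion(mode="bbs", bbs_inclusive=True), True),
            (dict(tug_seconds=14.0), FallCriterion(mode="tug"), False),
            (dict(tug_seconds=14.1), FallCriterion(mode="tug"), True),
            (dict(fell_within_3_months=True), FallCriterion(mode="history"), True),
            (dict(fell_within_3_months=False), FallCriterion(mode="history"), False),
        ],
    )
    def test_criterion_boundaries(self, kwargs, criterion, expected):
        assert label_faller(self.mk(**kwargs), criterion) is expected

    def test_missing_field_for_mode(self):
        with pytest.raises(DataError):
            label_faller(self.mk(tug_seconds=20.0), FallCriterion(mode="bbs"))

    def test_bbs_range_enforced(self):
        with pytest.raises(ValidationError):
            self.mk(bbs_score=57)


class TestRocCurve:
    def test_perfect_separation_reaches_corner(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        # passes through sensitivity 1, specificity 1
        hit = (roc.sensitivity == 1.0) & (roc.fpr == 0.0)
        assert hit.any()
        assert auc(roc) == 1.0

    def test_all_scores_equal_gives_diagonal(self):
        roc = roc_curve([0.5] * 6, [True, False, True, False, True, False])
        assert auc(roc) == pytest.approx(0.5)
        np.testing.assert_allclose(roc.sensitivity, roc.fpr)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            roc_curve([0.1, 0.2], [True, True])

    def test_monotone_coordinates(self):
        scores, labels = random_cohort(42)
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert roc.sensitivity[0] == 0 and roc.sensitivity[-1] == 1
        assert roc.fpr[0] == 0 and roc.fpr[-1] == 1


class TestAuc:
    def test_pair_counting_example(self):
        # 3 of the 4 (pos, neg) pairs correctly ordered
        a = auc(roc_curve([0.8, 0.4, 0.6, 0.2], [True, True, False, False]))
        assert a == pytest.approx(0.75)

    def test_label_inversion_complements(self):
        scores, labels = random_cohort(7, tie_prone=False)
        a = auc(roc_curve(scores, labels))
        a_inv = auc(roc_curve(scores, ~labels))
        assert a_inv == pytest.approx(1.0 - a)

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_equals_exhaustive_pair_counting(self, seed):
        scores, labels = random_cohort(seed)
        a = auc(roc_curve(scores, labels))
        assert a == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        scores, labels = random_cohort(seed, tie_prone=False)
        a = auc(roc_curve(scores, labels))
        for f in (lambda x: 3 * x + 2, np.exp, lambda x: x**3):
            assert auc(roc_curve(f(scores), labels)) == pytest.approx(a, abs=1e-12)

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        for _ in range(30):
            scores, labels = random_cohort(int(rng.integers(1 << 31)), max_n=40)
            assert auc(roc_curve(scores, labels)) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestAucSeCi:
    def test_degenerate_perfect_auc(self):
        roc = roc_curve([3.0, 2.0, 1.0, 0.0], [True, True, False, False])
        se, ci = auc_se_ci(roc)
        assert se == 0.0
        assert ci == (1.0, 1.0)

    def test_hanley_mcneil_hand_computation(self):
        a, n_pos, n_neg = 0.92, 20, 20
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        expect = np.sqrt(
            (a * (1 - a) + 19 * (q1 - a * a) + 19 * (q2 - a * a)) / 400
        )
        roc = RocSummary(
            thresholds=np.array([np.inf]),
            sensitivity=np.array([0.0]),
            fpr=np.array([0.0]),
            n_pos=n_pos,
            n_neg=n_neg,
            auc=a,
        )
        se, ci = auc_se_ci(roc)
        assert se == pytest.approx(expect, abs=1e-12)
        assert ci[0] == pytest.approx(max(0.0, a - 1.96 * expect))
        assert ci[1] <= 1.0

    def test_centered_at_half_for_uninformative(self):
        roc = RocSummary(
            thresholds=np.array([np.inf]),
            sensitivity=np.array([0.0]),
            fpr=np.array([0.0]),
            n_pos=500,
            n_neg=500,
            auc=0.5,
        )
        se, (lo, hi) = auc_se_ci(roc)
        assert lo + hi == pytest.approx(1.0)


class TestYouden:
    def test_forced_maximum(self):
        roc = RocSummary(
            thresholds=np.array([np.inf, 0.8, 0.5, 0.3]),
            sensitivity=np.array([0.0, 0.90, 0.60, 1.00]),
            fpr=np.array([0.0, 0.30, 0.10, 1.00]),
            n_pos=10,
            n_neg=10,
        )
        cutoff, j = youden_cutoff(roc)
        assert cutoff == 0.8 and j == pytest.approx(0.60)

    def test_diagonal_curve_j_zero(self):
        roc = roc_curve([0.5] * 4, [True, False, True, False])
        _, j = youden_cutoff(roc)
        assert j == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_never_beaten_by_any_threshold(self, seed):
        scores, labels = random_cohort(seed)
        roc = roc_curve(scores, labels)
        cutoff, j = youden_cutoff(roc)
        # exhaustive sweep over all candidate thresholds
        for thr in np.concatenate([scores, [np.inf, -np.inf]]):
            c = confusion(scores, labels, thr)
            m = metrics(c)
            assert m.sensitivity + m.specificity - 1 <= j + 1e-12
        # and the returned cut-off attains J
        m = metrics(confusion(scores, labels, cutoff))
        assert m.sensitivity + m.specificity - 1 == pytest.approx(j, abs=1e-12)


class TestConfusionAndMetrics:
    def test_counts_by_direct_enumeration(self):
        scores = [0.9, 0.7, 0.5, 0.3, 0.1]
        labels = [True, False, True, False, False]
        c = confusion(scores, labels, cutoff=0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 2, 0)

    def test_formulas(self):
        m = metrics(ConfusionCounts(tp=18, fn=2, tn=15, fp=5))
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.825)

    def test_sensitivity_by_formula(self):
        m = metrics(ConfusionCounts(tp=9, fn=1, tn=0, fp=2))
        assert m.sensitivity == pytest.approx(0.9)

    def test_all_correct(self):
        m = metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_zero_denominator_marks_nan(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert np.isnan(m.sensitivity)
        assert m.grades["sensitivity"] is None

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_balanced_accuracy_identity(self, seed):
        # with equal class sizes, accuracy = (sensitivity + specificity) / 2
        rng = np.random.default_rng(seed)
        n = 10
        scores = rng.normal(size=2 * n)
        labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        cutoff = float(rng.normal())
        m = metrics(confusion(scores, labels, cutoff))
        assert m.accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)


class TestGrading:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.92, "excellent"),
            (0.81, "excellent"),
            (1.0, "excellent"),
            (0.80, "good"),
            (0.70, "good"),
            (0.61, "good"),
            (0.60, "moderate"),
            (0.55, "moderate"),
            (0.41, "moderate"),
            (0.40, "poor"),
            (0.0, "poor"),
        ],
    )
    def test_bands(self, value, band):
        assert grade(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            grade(1.2)


class TestGroupCompare:
    def test_identical_groups(self):
        t, p = group_compare(1.0, 0.5, 10, 1.0, 0.5, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_age_summaries_clearly_different(self):
        # young adults vs older adults with MCI: 25.20±3.19 vs 79.00±8.25
        t, p = group_compare(25.20, 3.19, 20, 79.00, 8.25, 20)
        assert p < 0.001

    def test_matches_scipy_on_raw_samples(self, rng):
        from scipy import stats

        a = rng.normal(0.3, 1.0, 15)
        b = rng.normal(0.0, 2.0, 12)
        t, p = group_compare(a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1), 12)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize(
        "args", [(1, 0.5, 1, 0, 0.5, 10), (1, 0.0, 5, 0, 0.5, 10)]
    )
    def test_degenerate_inputs_rejected(self, args):
        with pytest.raises(ValidationError):
            group_compare(*args)


def test_summarize_roc_fills_all_fields():
    scores, labels = random_cohort(3)
    roc = summarize_roc(scores, labels)
    assert not np.isnan(roc.auc)
    assert not np.isnan(roc.se)
    assert 0 <= roc.ci95[0] <= roc.ci95[1] <= 1
    assert np.isfinite(roc.cutoff)
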