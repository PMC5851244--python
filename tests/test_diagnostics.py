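"""ROC/AUROC estimation, DeLong inference, paired tests, binomial CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepscore import (CiMethod, DegenerateInputError, GroupedScoreTable,
                      PairingError, auroc_from_grouped, auroc_mann_whitney,
                      binomial_ci, delong_variance, expand_grouped,
                      paired_delong_test, paired_sens_spec_test, roc_curve,
                      roc_from_grouped, sens_spec_at_cutoff,
                      sens_spec_from_grouped)

from conftest import brute_force_auc


class TestMannWhitneyAuroc:
    def test_matches_brute_force_oracle_on_random_ordinal_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 5, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            est = auroc_mann_whitney(scores, labels).auc
            assert est == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_with_ties(self, rng):
        roc_auc_score = pytest.importorskip("sklearn.metrics").roc_auc_score
        scores = rng.integers(0, 4, size=300).astype(float)
        labels = rng.integers(0, 2, size=300)
        assert auroc_mann_whitney(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_separable_and_constant(self):
        assert auroc_mann_whitney([1, 1, 9, 9], [0, 0, 1, 1]).auc == 1.0
        assert auroc_mann_whitney([5, 5, 5, 5], [0, 0, 1, 1]).auc == 0.5

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            auroc_mann_whitney([1, 2, 3], [1, 1, 1])

    def test_monotone_transform_invariance(self, rng):
        scores = rng.integers(0, 5, size=100).astype(float)
        labels = np.r_[np.zeros(60, int), np.ones(40, int)]
        a0 = auroc_mann_whitney(scores, labels).auc
        assert auroc_mann_whitney(np.exp(scores), labels).auc == pytest.approx(a0)
        assert auroc_mann_whitney(3 * scores - 7, labels).auc == pytest.approx(a0)

    def test_label_swap_symmetry(self, rng):
        scores = rng.integers(0, 5, size=80).astype(float)
        labels = rng.integers(0, 2, size=80)
        labels[0], labels[1] = 0, 1
        a = auroc_mann_whitney(scores, labels).auc
        assert auroc_mann_whitney(scores, 1 - labels).auc == pytest.approx(1 - a)


class TestGroupedAuroc:
    def test_published_tables(self, fixture_tables):
        assert auroc_from_grouped(fixture_tables.qsofa_table).auc == pytest.approx(
            0.717, abs=5e-4)
        assert auroc_from_grouped(fixture_tables.qsofa_lactate_table).auc == pytest.approx(
            0.754, abs=5e-4)
        assert auroc_from_grouped(fixture_tables.lactate_binary_table).auc == pytest.approx(
            0.659, abs=5e-4)

    def test_equals_expanded_computation(self, fixture_tables, small_table):
        for table in (small_table, fixture_tables.qsofa_table,
                      fixture_tables.qsofa_lactate_table):
            s, y = expand_grouped(table)
            assert auroc_from_grouped(table).auc == pytest.approx(
                auroc_mann_whitney(s, y).auc, abs=1e-15)

    def test_proportional_counts_give_half(self):
        t = GroupedScoreTable(levels=(0, 1, 2), counts_pos=(2, 4, 6),
                              counts_neg=(10, 20, 30))
        assert auroc_from_grouped(t).auc == pytest.approx(0.5)

    def test_binary_test_identity(self, fixture_tables):
        """For a dichotomous score, AUC = (sens + spec) / 2."""
        t = fixture_tables.lactate_binary_table
        perf = sens_spec_from_grouped(t, cutoff=1)
        auc = auroc_from_grouped(t).auc
        assert auc == pytest.approx((perf.sensitivity + perf.specificity) / 2,
                                    abs=1e-12)


class TestDelong:
    def test_separable_data_zero_se(self):
        assert delong_variance([1, 2, 8, 9], [0, 0, 1, 1]) == 0.0

    def test_label_swap_preserves_se(self, rng):
        scores = rng.integers(0, 5, size=60).astype(float)
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        assert delong_variance(scores, labels) == pytest.approx(
            delong_variance(scores, 1 - labels))

    def test_se_close_to_stratified_bootstrap(self, rng):
        """DeLong se within 10% of a 5000-rep stratified bootstrap."""
        pos = rng.integers(1, 6, size=30).astype(float)
        neg = rng.integers(0, 5, size=30).astype(float)
        scores = np.r_[neg, pos]
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        se = delong_variance(scores, labels)
        boot = np.empty(5000)
        for b in range(5000):
            rp = rng.choice(pos, size=30)
            rn = rng.choice(neg, size=30)
            boot[b] = brute_auc_fast(rp, rn)
        assert se == pytest.approx(boot.std(ddof=1), rel=0.10)

    def test_paired_identical_scores(self):
        labels = [0, 0, 0, 1, 1]
        s = [1.0, 2.0, 3.0, 2.0, 4.0]
        res = paired_delong_test(s, s, labels)
        assert res.delta == 0.0 and res.p == 1.0

    def test_paired_antisymmetry(self, rng):
        labels = np.r_[np.zeros(50, int), np.ones(30, int)]
        a = rng.integers(0, 5, size=80).astype(float)
        b = rng.integers(0, 5, size=80).astype(float)
        r_ab = paired_delong_test(a, b, labels)
        r_ba = paired_delong_test(b, a, labels)
        assert r_ab.delta == pytest.approx(-r_ba.delta)
        assert r_ab.p == pytest.approx(r_ba.p)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            paired_delong_test([1, 2], [1, 2, 3], [0, 1, 1])


def brute_auc_fast(pos, neg):
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size


class TestSensSpec:
    def test_published_operating_points(self, fixture_tables):
        q = sens_spec_from_grouped(fixture_tables.qsofa_table, cutoff=2)
        assert round(100 * q.sensitivity) == 46
        assert round(100 * q.specificity) == 86
        ql = sens_spec_from_grouped(fixture_tables.qsofa_lactate_table, cutoff=2)
        assert round(100 * ql.sensitivity) == 72
        assert round(100 * ql.specificity) == 73

    def test_cutoff_below_minimum(self):
        perf = sens_spec_at_cutoff([0, 1, 2, 3], [0, 0, 1, 1], cutoff=-1)
        assert perf.sensitivity == 1.0 and perf.specificity == 0.0

    def test_counts_partition_cohort(self, fixture_tables):
        t = fixture_tables.qsofa_table
        perf = sens_spec_from_grouped(t, cutoff=2)
        assert perf.tp + perf.fp + perf.tn + perf.fn == t.n

    def test_grouped_equals_expanded(self, fixture_tables):
        t = fixture_tables.qsofa_lactate_table
        s, y = expand_grouped(t)
        a = sens_spec_from_grouped(t, cutoff=2)
        b = sens_spec_at_cutoff(s, y, cutoff=2)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)


class TestBinomialCi:
    def test_wald_closed_form(self):
        lo, hi = binomial_ci(23, 50, 0.95, CiMethod.WALD)
        assert lo == pytest.approx(0.322, abs=5e-4)
        assert hi == pytest.approx(0.598, abs=5e-4)

    def test_boundaries_clipped(self):
        assert binomial_ci(50, 50, 0.95, CiMethod.EXACT)[1] == 1.0
        assert binomial_ci(0, 10, 0.95, CiMethod.WILSON)[0] == 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 3)

    @given(st.integers(0, 40), st.integers(1, 40))
    @settings(deadline=None, max_examples=50)
    def test_interval_contains_point_estimate(self, k, n):
        if k > n:
            return
        for method in CiMethod:
            lo, hi = binomial_ci(k, n, 0.95, method)
            assert 0 <= lo <= k / n + 1e-12
            assert k / n - 1e-12 <= hi <= 1


class TestPairedSensSpec:
    def test_identical_calls(self):
        calls = np.array([True, False, True, False, True])
        labels = np.array([1, 1, 0, 0, 1])
        res = paired_sens_spec_test(calls, calls, labels)
        assert res.sensitivity.p == 1.0
        assert res.specificity.p == 1.0
        assert res.joint.p == 1.0

    def test_one_sided_discordance_exact_binomial(self):
        """13 diseased discordant pairs all favouring test b:
        exact McNemar p = 2 * 0.5^13."""
        n_pos = 20
        a = np.zeros(n_pos, dtype=bool)
        b = np.zeros(n_pos, dtype=bool)
        b[:13] = True  # b positive where a negative
        a_full = np.r_[a, np.zeros(10, bool)]
        b_full = np.r_[b, np.zeros(10, bool)]
        labels = np.r_[np.ones(n_pos, int), np.zeros(10, int)]
        res = paired_sens_spec_test(a_full, b_full, labels)
        assert res.sensitivity.p == pytest.approx(2 * 0.5**13, rel=1e-9)
        assert res.sensitivity.p < 0.001

    def test_permutation_invariance(self, rng):
        n = 60
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.5
        labels = np.r_[np.ones(20, int), np.zeros(40, int)]
        perm = rng.permutation(n)
        r1 = paired_sens_spec_test(a, b, labels)
        r2 = paired_sens_spec_test(a[perm], b[perm], labels[perm])
        assert r1.sensitivity.p == pytest.approx(r2.sensitivity.p)
        assert r1.joint.statistic == pytest.approx(r2.joint.statistic)

    def test_delta_antisymmetry(self, rng):
        a = rng.random(50) < 0.6
        b = rng.random(50) < 0.4
        labels = np.r_[np.ones(25, int), np.zeros(25, int)]
        r_ab = paired_sens_spec_test(a, b, labels)
        r_ba = paired_sens_spec_test(b, a, labels)
        assert r_ab.sensitivity.delta == pytest.approx(-r_ba.sensitivity.delta)
        assert r_ab.specificity.delta == pytest.approx(-r_ba.specificity.delta)


class TestRocCurve:
    def test_area_equals_mann_whitney(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 5, size=100).astype(float)
            labels = rng.integers(0, 2, size=100)
            if labels.sum() in (0, 100):
                continue
            curve = roc_curve(scores, labels)
            assert curve.area() == pytest.approx(
                auroc_mann_whitney(scores, labels).auc, abs=1e-12)

    def test_binary_lactate_operating_point(self, fixture_tables):
        curve = roc_from_grouped(fixture_tables.lactate_binary_table)
        # middle point: positive call at level >= 1
        pts = {t: (tpr, fpr) for t, tpr, fpr in curve.points}
        tpr, fpr = pts[1.0]
        assert tpr == pytest.approx(0.72, abs=5e-3)
        assert fpr == pytest.approx(0.403, abs=5e-3)

    def test_constant_score_diagonal(self):
        curve = roc_curve([3, 3, 3, 3], [0, 1, 0, 1])
        assert curve.area() == pytest.approx(0.5)

    def test_separable_through_corner(self):
        curve = roc_curve([1, 2, 8, 9], [0, 0, 1, 1])
        assert (8.0, 1.0, 0.0) in curve.points
        assert curve.area() == 1.0

    def test_rates_monotone_in_threshold(self, rng):
        scores = rng.integers(0, 6, size=80).astype(float)
        labels = np.r_[np.ones(30, int), np.zeros(50, int)]
        curve = roc_curve(scores, labels)
        tprs = [p[1] for p in curve.points]
        fprs = [p[2] for p in curve.points]
        assert all(a >= b for a, b in zip(tprs, tprs[1:]))
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))
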