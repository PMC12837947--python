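"""Confusion metrics, partitioning, CV intervals, permutation test,
calibration and the PR curve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigcough import (ConfusionCounts, ValidationError, basic_metrics,
                      confusion, kfold_indices, permutation_test, pr_auprc,
                      reliability_ece, stratified_split,
                      t_confidence_interval)
from pigcough.metrics import summarize_cv, MetricsReport


class TestConfusion:
    def test_perfect_classifier(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.fp, c.fn) == (0, 0) and c.tp == 2 and c.tn == 1

    def test_all_noise_on_all_cough(self):
        c = confusion(np.zeros(5), np.ones(5))
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 0, 5)

    def test_matches_per_sample_loop(self, rng):
        pred = rng.integers(0, 2, 20)
        true = rng.integers(0, 2, 20)
        c = confusion(pred, true)
        tp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 1)
        tn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 0)
        fp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 0)
        fn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 1)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion([1, 0], [1])


class TestBasicMetrics:
    def test_small_test_set_counts(self):
        """Counts from a 19-sample evaluation: 7 coughs all recovered, one
        false alarm."""
        r = basic_metrics(ConfusionCounts(tp=7, tn=11, fp=1, fn=0))
        assert round(100 * r.accuracy, 2) == 94.74
        assert round(100 * r.precision, 2) == 87.50
        assert round(100 * r.recall, 2) == 100.00
        assert round(100 * r.f1, 2) == 93.33

    def test_perfect(self):
        r = basic_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (r.accuracy, r.precision, r.recall, r.f1) == (1, 1, 1, 1)

    def test_zero_tp_forces_zero_recall_f1(self):
        r = basic_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=2))
        assert r.recall == 0.0 and r.f1 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            basic_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_f1_is_harmonic_mean(self, tp, tn, fp, fn):
        r = basic_metrics(ConfusionCounts(tp, tn, fp, fn))
        if r.precision > 0 and r.recall > 0:
            hm = 2 * r.precision * r.recall / (r.precision + r.recall)
            assert np.isclose(r.f1, hm)


class TestStratifiedSplit:
    def test_study_scale_gives_105_test(self):
        labels = np.array([1] * 107 + [0] * 590)
        tv, te = stratified_split(labels, 0.15, seed=0)
        assert te.size == 105
        assert tv.size == 592

    def test_balanced_within_one(self):
        labels = np.array([1] * 50 + [0] * 50)
        tv, te = stratified_split(labels, 0.15, seed=1)
        assert te.size == 15
        assert abs(int(labels[te].sum()) - 7.5) <= 0.5 + 1

    def test_partition_properties(self, rng):
        labels = rng.integers(0, 2, 80)
        labels[:5] = 1
        labels[5:10] = 0
        tv, te = stratified_split(labels, 0.2, seed=2)
        assert np.intersect1d(tv, te).size == 0
        assert np.union1d(tv, te).size == 80

    def test_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_split(np.array([1, 0, 0, 0]), 0.15, 0)


class TestCvSummary:
    def test_zero_variance_zero_width(self):
        reports = [MetricsReport(0.9, 0.9, 0.9, 0.9)] * 5
        res = summarize_cv(reports)
        assert res.ci_low["accuracy"] == res.ci_high["accuracy"] == 0.9

    def test_t_interval_worked_example(self):
        """Five fold accuracies 0.90..0.98: mean 0.94, t(4)-based 95% CI
        [0.9007, 0.9793]."""
        mean, s, lo, hi = t_confidence_interval(
            np.array([0.90, 0.92, 0.94, 0.96, 0.98]))
        assert np.isclose(mean, 0.94)
        assert np.isclose(s, 0.031623, atol=1e-6)
        assert round(lo, 4) == 0.9007
        assert round(hi, 4) == 0.9793

    def test_fold_structure(self):
        labels = np.array([1] * 20 + [0] * 35)
        folds = kfold_indices(labels, k=5, seed=3)
        all_val = np.concatenate([va for _, va in folds])
        assert np.array_equal(np.sort(all_val), np.arange(55))
        sizes = [va.size for _, va in folds]
        assert max(sizes) - min(sizes) <= 1
        pos_counts = [int(labels[va].sum()) for _, va in folds]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_class_below_k_rejected(self):
        with pytest.raises(ValidationError):
            kfold_indices(np.array([1, 1, 0, 0, 0, 0, 0]), k=5)


def _acc(pred, true):
    return float(np.mean(np.asarray(pred) == np.asarray(true)))


class TestPermutationTest:
    def test_lower_bound_when_true_score_wins(self):
        """A perfect classifier on imbalanced labels: no permutation can
        reach the true score, so p = 1/101."""
        true = np.array([1] * 3 + [0] * 40)
        res = permutation_test(_acc, true.copy(), true, 100, seed=0)
        assert np.isclose(res.p_value, 1 / 101)
        assert res.p_value >= 1 / 101  # formula lower bound

    def test_p_one_when_all_permutations_tie(self):
        # constant predictions: every permuted accuracy equals the true one
        true = np.array([1, 1, 0, 0, 0, 0])
        pred = np.zeros(6)
        res = permutation_test(_acc, pred, true, 50, seed=1)
        assert res.p_value == 1.0

    def test_seed_reproducible(self):
        true = np.array([1] * 5 + [0] * 15)
        pred = np.array([1] * 4 + [0] * 16)
        a = permutation_test(_acc, pred, true, 30, seed=7)
        b = permutation_test(_acc, pred, true, 30, seed=7)
        assert np.array_equal(a.s_perm, b.s_perm) and a.p_value == b.p_value

    def test_constant_labels_rejected(self):
        with pytest.raises(ValidationError):
            permutation_test(_acc, np.ones(4), np.ones(4), 10)


class TestCalibration:
    def test_single_bin_hand_case(self):
        """10 predictions at confidence 0.9 of which 6 are coughs:
        ECE = |0.6 - 0.9| = 0.3."""
        p = np.full(10, 0.9)
        y = np.array([1] * 6 + [0] * 4)
        rep = reliability_ece(p, y, m_bins=10)
        assert np.isclose(rep.ece, 0.3)
        assert rep.bin_counts.sum() == 10

    def test_perfectly_calibrated_bins_zero(self):
        # two bins, each with accuracy equal to mean confidence
        p = np.array([0.2] * 5 + [0.8] * 5)
        y = np.array([1, 0, 0, 0, 0] + [1, 1, 1, 1, 0])
        rep = reliability_ece(p, y, m_bins=5)
        assert np.isclose(rep.ece, 0.0)

    def test_two_bin_loop_oracle(self):
        p = np.array([0.1, 0.15, 0.7, 0.75])
        y = np.array([0, 1, 1, 1])
        rep = reliability_ece(p, y, m_bins=2)
        lo = [0, 1]
        hi = [2, 3]
        expected = (2 / 4) * abs(np.mean(y[lo]) - np.mean(p[lo])) \
            + (2 / 4) * abs(np.mean(y[hi]) - np.mean(p[hi]))
        assert np.isclose(rep.ece, expected)

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 200)
        y = rng.integers(0, 2, 200)
        perm = rng.permutation(200)
        assert np.isclose(reliability_ece(p, y).ece,
                          reliability_ece(p[perm], y[perm]).ece)

    def test_calibrated_oracle_near_zero(self):
        """Labels drawn as Bernoulli(p) make p perfectly calibrated."""
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 20000)
        y = (rng.uniform(0, 1, 20000) < p).astype(int)
        assert reliability_ece(p, y).ece < 0.02

    def test_edge_assignment(self):
        rep = reliability_ece(np.array([0.0, 0.1, 1.0]),
                              np.array([0, 0, 1]), m_bins=10)
        assert rep.bin_counts[0] == 2   # 0.0 and the right edge 0.1
        assert rep.bin_counts[9] == 1   # 1.0 in the top bin

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            reliability_ece(np.array([]), np.array([]))


class TestPrCurve:
    def test_perfect_ranking(self):
        curve = pr_auprc(np.array([0.9, 0.8, 0.2, 0.1]),
                         np.array([1, 1, 0, 0]))
        assert curve.auprc == 1.0

    def test_inverted_ranking_hits_prevalence(self):
        """Scores anti-correlated with labels floor the step-wise AP at the
        positive prevalence (4-point toy curve enumerated by hand)."""
        y = np.array([1, 1, 0, 0])
        curve = pr_auprc(1.0 - y, y)
        assert np.isclose(curve.auprc, 0.5)

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score
        for trial in range(10):
            r = np.random.default_rng(trial)
            y = r.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            s = r.uniform(0, 1, 30)
            assert np.isclose(pr_auprc(s, y).auprc,
                              average_precision_score(y, s))

    def test_six_sample_brute_force(self):
        s = np.array([0.9, 0.7, 0.6, 0.4, 0.3, 0.1])
        y = np.array([1, 0, 1, 1, 0, 0])
        curve = pr_auprc(s, y)
        # enumerate all thresholds by hand
        pts = []
        for thr in sorted(set(s), reverse=True):
            pred = s >= thr
            tp = int(np.sum(pred & (y == 1)))
            fp = int(np.sum(pred & (y == 0)))
            pts.append((tp / 3, tp / (tp + fp)))
        ap = sum((r - r_prev) * p for (r, p), r_prev
                 in zip(pts, [0.0] + [r for r, _ in pts[:-1]]))
        assert np.isclose(curve.auprc, ap)

    def test_recall_monotone(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        curve = pr_auprc(rng.uniform(0, 1, 50), y)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            pr_auprc(np.array([0.1, 0.2]), np.array([1, 1]))
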