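import math

import numpy as np
import pytest

from intercoev import evaluation as ev
from intercoev.errors import EvaluationError


class TestConfusion:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        ct = ev.confusion(scores, labels, 0.5)
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (2, 0, 2, 0)

    def test_threshold_above_everything(self):
        ct = ev.confusion([0.1, 0.2], [True, False], 0.5)
        assert ct.tp == 0 and ct.fp == 0 and ct.fn == 1 and ct.tn == 1

    def test_enumerated_counts(self):
        # 10 cells, 4 positives, top-5 threshold captures 3 positives
        scores = np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1], dtype=float)
        labels = np.array([1, 1, 0, 1, 0, 0, 1, 0, 0, 0], dtype=bool)
        ct = ev.confusion(scores, labels, 6.0)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (3, 2, 1, 4)

    def test_pvalue_orientation(self):
        ct = ev.confusion([0.01, 0.5], [True, False], 0.05, orientation="lower")
        assert ct.tp == 1 and ct.fp == 0


class TestMetrics:
    def test_derived_arithmetic(self):
        op = ev.metrics(ev.ConfusionTable(tp=90, fp=10, tn=890, fn=10))
        assert op.tpr == pytest.approx(0.9)
        assert op.fpr == pytest.approx(10 / 900)
        assert op.ppv == pytest.approx(0.9)
        assert op.f1 == pytest.approx(0.9)
        assert op.phi == pytest.approx((90 * 890 - 10 * 10) / math.sqrt(100 * 900 * 100 * 900))

    def test_no_information_point(self):
        op = ev.metrics(ev.ConfusionTable(tp=5, fn=5, fp=7, tn=7))
        assert op.tpr == pytest.approx(0.5)
        assert op.fpr == pytest.approx(0.5)
        assert op.phi == pytest.approx(0.0)

    def test_all_correct(self):
        op = ev.metrics(ev.ConfusionTable(tp=4, fp=0, tn=6, fn=0))
        assert (op.tpr, op.ppv, op.f1, op.phi) == (1.0, 1.0, 1.0, 1.0)
        assert op.fpr == 0.0

    def test_undefined_ratios_masked_not_zero(self):
        op = ev.metrics(ev.ConfusionTable(tp=0, fp=0, tn=5, fn=3))
        assert math.isnan(op.ppv) and math.isnan(op.f1) and math.isnan(op.phi)

    def test_matches_recomputation_from_predictions(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            op = ev.metrics(ev.ConfusionTable(int(tp), int(fp), int(tn), int(fn)))
            assert op.tpr == pytest.approx(tp / (tp + fn))
            assert op.fpr == pytest.approx(fp / (fp + tn))
            if tp + fp:
                assert op.ppv == pytest.approx(tp / (tp + fp))


class TestCurves:
    def test_perfect_scores(self):
        scores = np.array([3.0, 2.0, 1.0, 0.5])
        labels = np.array([True, True, False, False])
        c = ev.roc_pr_curves(scores, labels)
        assert c.auroc == 1.0 and c.aupr == 1.0 and c.f_max == 1.0

    def test_auroc_equals_mann_whitney(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.3
        if not labels.any() or labels.all():
            labels[0] = True
            labels[1] = False
        pos = scores[labels]
        neg = scores[~labels]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = u / (pos.size * neg.size)
        assert ev.roc_pr_curves(scores, labels).auroc == pytest.approx(expected, abs=1e-12)

    def test_orientation_reversal_flips_auroc(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[:2] = [True, False]
        a1 = ev.roc_pr_curves(scores, labels, "higher").auroc
        a2 = ev.roc_pr_curves(scores, labels, "lower").auroc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_random_scores_auroc_near_half(self):
        aurocs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            scores = r.normal(size=400)
            labels = r.random(400) < 0.2
            aurocs.append(ev.roc_pr_curves(scores, labels).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.05

    def test_aupr_matches_step_interpolation_oracle(self, rng):
        from sklearn.metrics import average_precision_score

        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.3
        labels[:2] = [True, False]
        c = ev.roc_pr_curves(scores, labels)
        assert c.aupr == pytest.approx(average_precision_score(labels, scores), abs=1e-12)

    def test_one_class_error(self):
        with pytest.raises(EvaluationError):
            ev.roc_pr_curves([1.0, 2.0], [True, True])


class TestPowerAtFpr:
    def test_perfect_separation_full_power(self):
        scores = np.array([3.0, 2.0, 1.0, 0.5])
        labels = np.array([True, True, False, False])
        op = ev.power_at_fpr(scores, labels, 0.05)
        assert op.tpr == 1.0 and op.fpr == 0.0

    def test_alpha_below_resolution_forbids_any_fp(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.3
        labels[:2] = [True, False]
        op = ev.power_at_fpr(scores, labels, alpha=1.0 / (~labels).sum())
        assert op.fpr == 0.0

    def test_forced_top_false_positive_blocks_predictions(self):
        # strongest score is a negative: at strict alpha nothing above it counts
        n_neg = 1000
        scores = np.r_[5.0, np.linspace(4, 3, 10), np.linspace(2, 1, n_neg - 1)]
        labels = np.r_[False, np.ones(10, bool), np.zeros(n_neg - 1, bool)]
        op = ev.power_at_fpr(scores, labels, alpha=0.001)
        assert op.tpr == 0.0  # any positive prediction would include the FP

    def test_monotone_in_alpha(self, rng):
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(scale=1.5, size=300)) > 1.0
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        tpr_loose = ev.power_at_fpr(scores, labels, 0.05).tpr
        tpr_strict = ev.power_at_fpr(scores, labels, 0.001).tpr
        assert tpr_loose >= tpr_strict


class TestNominalFpr:
    def test_all_pvalues_one(self):
        nom, ratio = ev.nominal_fpr([1.0, 1.0, 1.0], [False] * 3, 0.05)
        assert nom == 0.0

    def test_all_pvalues_zero(self):
        nom, _ = ev.nominal_fpr([0.0, 0.0], [False, False], 0.05)
        assert nom == 1.0

    def test_uniform_null_calibrated(self):
        devs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            p = r.uniform(size=2000)
            nom, ratio = ev.nominal_fpr(p, np.zeros(2000, bool), 0.05)
            devs.append(nom - 0.05)
        tol = 3 * math.sqrt(0.05 * 0.95 / 2000)
        assert abs(np.mean(devs)) < tol

    def test_positives_excluded(self):
        p = np.array([0.001, 0.9])
        labels = np.array([True, False])
        nom, _ = ev.nominal_fpr(p, labels, 0.05)
        assert nom == 0.0


class TestEntropyStratified:
    def metric(self, v, y):
        return ev.roc_pr_curves(v, y).auroc

    def test_partition_sizes_sum(self, rng):
        la, lb = 6, 8
        v = rng.normal(size=(la, lb))
        y = rng.random((la, lb)) < 0.3
        y[0, 0] = True
        y[1, 1] = False
        hA = rng.uniform(0, 2, la)
        hB = rng.uniform(0, 2, lb)
        sizes = 0
        medA, medB = np.median(hA), np.median(hB)
        for ga in ("low", "high"):
            for gb in ("low", "high"):
                selA = (hA > medA) == (ga == "high")
                selB = (hB > medB) == (gb == "high")
                sizes += selA.sum() * selB.sum()
        assert sizes == la * lb

    def test_tied_entropies_collapse_to_low_group(self, rng):
        v = rng.normal(size=(4, 4))
        y = rng.random((4, 4)) < 0.5
        y[0, 0], y[1, 1] = True, False
        out = ev.entropy_stratified_eval(v, y, np.ones(4), np.ones(4), self.metric)
        assert not math.isnan(out[("low", "low")])
        assert all(
            math.isnan(out[g]) for g in [("low", "high"), ("high", "low"), ("high", "high")]
        )

    def test_signal_isolated_in_high_high_group(self):
        rng = np.random.default_rng(1)
        la = lb = 8
        hA = np.r_[np.zeros(4), np.ones(4)]
        hB = np.r_[np.zeros(4), np.ones(4)]
        v = rng.normal(size=(la, lb)) * 0.01
        y = np.zeros((la, lb), bool)
        # plant perfect signal among high-entropy columns only
        v[5, 5] = v[6, 6] = 10.0
        y[5, 5] = y[6, 6] = True
        y[4, 7] = False
        out = ev.entropy_stratified_eval(v, y, hA, hB, self.metric)
        assert out[("high", "high")] == pytest.approx(1.0)
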