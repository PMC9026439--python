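"""Statistics tests: confusion counting against enumeration, the metric
panel on worked examples, the AUC/Mann-Whitney identity, DeLong
variance against a bootstrap, the paired DeLong test against swap
permutations, and the printed-panel inversion."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from dbnn.evaluation import (ConfusionCounts, confusion, metrics, roc_auc,
                             auc_mann_whitney, delong_ci, delong_variance,
                             delong_test, mann_whitney, reconstruct_confusion,
                             full_report, aggregate_patients)
from dbnn.errors import ValidationError, ContractError, ReconstructionError


class TestConfusion:
    def test_all_correct_has_no_errors(self):
        c = confusion([0.9, 0.8, 0.1], [1, 1, 0])
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 1)

    def test_zero_threshold_predicts_everything_positive(self, rng):
        c = confusion(rng.random(30), rng.integers(0, 2, 30), threshold=0.0)
        assert c.tn == 0 and c.fn == 0

    def test_matches_per_item_enumeration(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        c = confusion(scores, labels, 0.5)
        tp = sum(1 for s, l in zip(scores, labels) if s >= 0.5 and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= 0.5 and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s < 0.5 and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s < 0.5 and l == 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValidationError):
            confusion([], [])
        with pytest.raises(ContractError):
            confusion([0.5], [1, 0])


class TestMetrics:
    def test_reported_test_panel_worked_example(self):
        """68/17/7/100 on 75 positives and 117 negatives reproduces the
        printed panel: F1 0.850, accuracy 87.5%, sensitivity 90.67%,
        PPV 80.00%, NPV 93.46%."""
        rep = metrics(ConfusionCounts(tp=68, fp=17, fn=7, tn=100))
        assert round(rep.f1, 3) == 0.850
        assert round(100 * rep.accuracy, 2) == 87.50
        assert round(100 * rep.sensitivity, 2) == 90.67
        assert round(100 * rep.ppv, 2) == 80.00
        assert round(100 * rep.npv, 2) == 93.46

    def test_perfect_classifier_all_ones(self):
        rep = metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert all(getattr(rep, k) == 1.0 for k in
                   ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1"))

    def test_unit_counts_hand_arithmetic(self):
        rep = metrics(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        assert rep.accuracy == rep.sensitivity == rep.specificity == 0.5
        assert rep.ppv == rep.npv == 0.5
        assert rep.f1 == pytest.approx(0.5)      # 2*1 / (2*1 + 1 + 1)

    def test_degenerate_cells_are_none_not_zero(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert rep.ppv is None
        assert "ppv" in rep.undefined_fields()

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(1, 50, 4)
            rep = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            hm = 2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity)
            assert rep.f1 == pytest.approx(hm)


class TestAuc:
    def test_perfect_separation_gives_one(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([0.5] * 10, [1] * 4 + [0] * 6)
        assert auc == 0.5

    def test_matches_exhaustive_pair_count(self, rng):
        for _ in range(50):
            scores = np.round(rng.random(12), 2)   # rounding forces some ties
            labels = np.array([1] * 6 + [0] * 6)
            rng.shuffle(labels)
            if labels.sum() in (0, 12):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = [(1.0 if x > y else 0.5 if x == y else 0.0)
                     for x, y in itertools.product(pos, neg)]
            assert auc_mann_whitney(scores, labels) == pytest.approx(np.mean(pairs))

    def test_agrees_with_sklearn(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        if 0 < labels.sum() < 50:
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores))

    def test_auc_u_statistic_identity(self, rng):
        """AUC equals U / (n_pos * n_neg) on identical data."""
        pos = rng.normal(1, 1, 9)
        neg = rng.normal(0, 1, 7)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 9 + [0] * 7)
        u, _ = mann_whitney(pos, neg)
        assert auc_mann_whitney(scores, labels) == pytest.approx(u / (9 * 7))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        a1 = auc_mann_whitney(scores, labels)
        a2 = auc_mann_whitney(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)
        c1 = confusion(scores, labels, 0.5)
        c2 = confusion(np.exp(3 * scores), labels, np.exp(3 * 0.5))
        assert c1 == c2

    def test_roc_curve_is_monotone(self, rng):
        curve, _ = roc_auc(rng.random(40), [1] * 20 + [0] * 20)
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()
        assert curve.fpr[0] == 0 and curve.fpr[-1] == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_perfect_separation_zero_variance_ci(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.05]
        labels = [1, 1, 1, 0, 0, 0]
        auc, lo, hi = delong_ci(scores, labels)
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_variance_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        _, var = delong_variance(scores, labels)
        boots = []
        for _ in range(2000):
            ip = rng.integers(0, 30, 30)
            ineg = 30 + rng.integers(0, 30, 30)
            idx = np.concatenate([ip, ineg])
            boots.append(auc_mann_whitney(scores[idx], labels[idx]))
        bvar = np.var(boots, ddof=1)
        assert abs(var - bvar) / bvar < 0.2

    def test_identical_scores_give_z_zero_p_one(self, rng):
        scores = rng.random(30)
        labels = np.array([1] * 12 + [0] * 18)
        z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry_under_model_swap(self, rng):
        a, b = rng.random(40), rng.random(40)
        labels = np.array([1] * 15 + [0] * 25)
        z1, p1 = delong_test(a, b, labels)
        z2, p2 = delong_test(b, a, labels)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ContractError):
            delong_test(rng.random(5), rng.random(6), [1, 0, 1, 0, 1])


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney(x, list(x))
        assert p > 0.9

    def test_textbook_example_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_agrees_with_enumeration_for_all_tie_free_3x3(self):
        """Exact two-sided p from the 20-arrangement null for every
        3+3 split of six distinct values."""
        values = [1, 2, 5, 8, 9, 12]
        for xs in itertools.combinations(values, 3):
            ys = [v for v in values if v not in xs]
            u_obs, p_obs = mann_whitney(list(xs), ys)
            # enumerate all C(6,3) assignments of the pooled values
            us = []
            for assign in itertools.combinations(values, 3):
                rest = [v for v in values if v not in assign]
                us.append(sum(1 for a in assign for b in rest if a > b))
            us = np.array(us)
            cdf = np.mean(us <= u_obs)
            sf = np.mean(us >= u_obs)
            p_exact = min(1.0, 2 * min(cdf, sf))
            assert p_obs == pytest.approx(p_exact)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestReconstruction:
    def test_printed_panel_inverts_to_unique_counts(self):
        c = reconstruct_confusion(87.50, 90.67, 75, 117)
        assert c == ConfusionCounts(tp=68, fp=17, fn=7, tn=100)

    def test_perfect_panel(self):
        assert reconstruct_confusion(100.0, 100.0, 10, 10) == \
            ConfusionCounts(10, 0, 0, 10)

    def test_inconsistent_panel_reports_failure(self):
        with pytest.raises(ReconstructionError):
            reconstruct_confusion(99.99, 50.0, 3, 3)

    def test_ambiguous_panel_reports_multiplicity(self):
        # with 0 decimals many (tp, tn) combinations round identically
        with pytest.raises(ReconstructionError) as e:
            reconstruct_confusion(50.0, 50.0, 100, 100, decimals=0)
        assert len(e.value.candidates) > 1

    def test_roundtrip_identity_on_random_counts(self, rng):
        for _ in range(500):
            tp, fn = rng.integers(0, 80), rng.integers(0, 80)
            fp, tn = rng.integers(0, 80), rng.integers(0, 80)
            c = ConfusionCounts(int(tp), int(fp), int(fn), int(tn))
            if c.n_pos < 1 or c.n_neg < 1:
                continue
            rep = metrics(c)
            try:
                back = reconstruct_confusion(100 * rep.accuracy,
                                             100 * rep.sensitivity,
                                             c.n_pos, c.n_neg, decimals=4)
            except ReconstructionError:
                continue    # a genuinely ambiguous panel is a valid outcome
            assert back == c


class TestAggregation:
    def test_patient_mean_aggregate(self):
        scores = np.array([0.9, 0.7, 0.1, 0.3])
        labels = np.array([1, 1, 0, 0])
        pids = ["a", "a", "b", "b"]
        s, l = aggregate_patients(scores, labels, pids)
        assert np.allclose(sorted(s), [0.2, 0.8])

    def test_full_report_includes_ci(self, rng):
        scores = rng.random(40)
        labels = np.array([1] * 15 + [0] * 25)
        rep = full_report(scores, labels)
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
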