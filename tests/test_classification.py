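import numpy as np
import pytest
from scipy.optimize import minimize

from hyperbrain.classification import (CVConfig, cross_validate,
                                       permutation_test, relief_weights,
                                       roc_auc, svm_fit_predict)
from conftest import cohort_and_networks, reduced_cv
from oracles import auc_pairs, relief_brute


class TestSVM:
    def test_separable_block_kernel_zero_training_error(self):
        k = np.kron(np.eye(2), np.ones((4, 4))) + 0.01 * np.eye(8)
        y = np.array([0] * 4 + [1] * 4)
        pred, _ = svm_fit_predict(k, y, k, cost=10.0)
        np.testing.assert_array_equal(pred, y)

    def test_single_class_fold_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            svm_fit_predict(np.eye(3), np.zeros(3, dtype=int), np.eye(3))

    def test_dual_solution_matches_qp_oracle(self):
        """6-point 1-D linear-kernel SVM against a direct solve of the
        soft-margin dual by constrained optimization."""
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1])
        ysign = 2.0 * y - 1
        c = 1.0
        k = x @ x.T
        _, dec = svm_fit_predict(k, y, k, cost=c)

        q = (ysign[:, None] * ysign[None, :]) * k

        def neg_dual(a):
            return 0.5 * a @ q @ a - a.sum()

        res = minimize(neg_dual, np.full(6, 0.1), method="SLSQP",
                       bounds=[(0, c)] * 6,
                       constraints={"type": "eq",
                                    "fun": lambda a: a @ ysign})
        a = res.x
        sv = (a > 1e-6) & (a < c - 1e-6)
        w = (a * ysign) @ x[:, 0]
        b = np.mean(ysign[sv] - w * x[sv, 0])
        np.testing.assert_allclose(dec, w * x[:, 0] + b, atol=1e-4)


class TestROC:
    def test_perfect_and_reversed_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)[0] == 1.0
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y)[0] == 0.0

    def test_hand_case_from_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        auc, pts = roc_auc(scores, y)
        assert auc == pytest.approx(0.75)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_equals_pair_counting_with_ties(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 12)
            if y.min() == y.max():
                continue
            scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=12)
            if np.ptp(scores) == 0:
                continue
            auc, _ = roc_auc(scores, y)
            assert auc == pytest.approx(auc_pairs(scores, y))

    def test_constant_scores_warn_and_return_half(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            auc, _ = roc_auc(np.ones(4), np.array([0, 0, 1, 1]))
        assert auc == 0.5


class TestRelief:
    def test_constant_feature_zero_weight(self, rng):
        x = np.column_stack([np.full(10, 3.0), rng.random(10)])
        w = relief_weights(x, np.array([0, 1] * 5))
        assert w[0] == 0.0

    def test_label_aligned_feature_dominates(self, rng):
        y = np.array([0] * 6 + [1] * 6)
        x = np.column_stack([y.astype(float), rng.random(12)])
        w = relief_weights(x, y)
        assert w[0] > w[1]

    def test_matches_brute_force_oracle(self, rng):
        x = rng.random((8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        np.testing.assert_allclose(relief_weights(x, y), relief_brute(x, y),
                                   atol=1e-12)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="2 instances"):
            relief_weights(np.random.default_rng(0).random((4, 2)),
                           np.array([0, 0, 0, 1]))


class TestPermutationTest:
    def test_extreme_observed_gives_minimal_p(self):
        labels = np.arange(10)

        def stat(lab):
            return 100.0 if np.array_equal(lab, labels) else 0.0

        assert permutation_test(stat, labels, 99, seed=0) == pytest.approx(1 / 100)

    def test_observed_below_everything_gives_one(self):
        labels = np.arange(10)

        def stat(lab):
            return -100.0 if np.array_equal(lab, labels) else 0.0

        assert permutation_test(stat, labels, 99, seed=0) == 1.0

    def test_super_uniform_under_null(self):
        """For a label-equivariant statistic on exchangeable data the
        permutation p-value is super-uniform."""
        rng = np.random.default_rng(42)
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            x = rng.standard_normal(20)
            labels = np.array([0] * 10 + [1] * 10)

            def stat(lab, x=x):
                return x[lab == 1].mean() - x[lab == 0].mean()

            p = permutation_test(stat, labels, 99,
                                 seed=int(rng.integers(2 ** 31)))
            hits += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_runs)
        assert hits / n_runs <= 0.05 + 3 * se


class TestCrossValidate:
    def test_duplicated_subjects_classified_perfectly(self):
        # 30 identical copies of one network per group, with disjoint
        # edge structure: every test subject has training twins, so
        # separation is self-evident and accuracy must be perfect
        from conftest import make_network
        net0 = make_network([{0, 1, 2}, {1, 2, 3}], 10)
        net1 = make_network([{4, 5, 6}, {5, 6, 7}], 10)
        nets = [net0] * 30 + [net1] * 30
        y = np.array([0] * 30 + [1] * 30)
        rep = cross_validate(nets, y, reduced_cv(3, n_repeats=1))
        assert rep.accuracy == 1.0

    def test_same_seed_identical_report(self):
        cohort, networks = cohort_and_networks(1, 1.0, n_per_group=12,
                                               n_rois=12, n_timepoints=80,
                                               n_perturbed=3)
        cv = reduced_cv(5, n_repeats=2)
        a = cross_validate(networks, cohort.labels, cv)
        b = cross_validate(networks, cohort.labels, cv)
        assert a.to_json() == b.to_json()

    def test_metric_identities(self):
        cohort, networks = cohort_and_networks(1, 1.0, n_per_group=12,
                                               n_rois=12, n_timepoints=80,
                                               n_perturbed=3)
        rep = cross_validate(networks, cohort.labels,
                             reduced_cv(9, n_repeats=1))
        n = len(cohort)
        n1 = int(cohort.labels.sum())
        n0 = n - n1
        acc = rep.per_repeat_accuracy[0]
        sen = rep.per_repeat_sensitivity[0]
        spe = rep.per_repeat_specificity[0]
        # accuracy = (TP + TN) / n with TP = sen*n1, TN = spe*n0
        assert acc * n == pytest.approx(sen * n1 + spe * n0, abs=1e-9)
        assert 0 <= rep.auc <= 1

    def test_too_few_subjects_per_class_rejected(self):
        cohort, networks = cohort_and_networks(1, 1.0, n_per_group=12,
                                               n_rois=12, n_timepoints=80,
                                               n_perturbed=3)
        cv = CVConfig(n_folds=20, n_repeats=1)
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(networks, cohort.labels, cv)
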