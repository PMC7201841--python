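"""Dual SVM solver, kernel, grid search, splitting and evaluation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from craniosex.svm import (
    EvalReport,
    Standardizer,
    correct_rate,
    decision_function,
    evaluate,
    grid_search,
    predict,
    rbf_kernel,
    rbf_kernel_matrix,
    solve_dual,
    stratified_split,
    C_EXPONENTS,
    DELTA_EXPONENTS,
)


def qp_oracle(X, y, C, delta):
    """Independent brute-force dual solution via constrained SLSQP."""
    K = rbf_kernel_matrix(X, X, delta)
    m = len(y)

    def neg_dual(a):
        ay = a * y
        return -(a.sum() - 0.5 * ay @ K @ ay)

    best = None
    for start in (np.zeros(m), np.full(m, 0.5 * min(C, 1.0))):
        res = minimize(neg_dual, start, method="SLSQP",
                       bounds=[(0.0, C)] * m,
                       constraints={"type": "eq", "fun": lambda a: a @ y},
                       options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x


class TestStandardizer:
    def test_training_set_zscored(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.0, size=(50, 4))
        Z = Standardizer.fit(X).transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_passthrough_with_warning(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.warns(UserWarning, match="constant feature"):
            scaler = Standardizer.fit(X)
        Z = scaler.transform(X)
        np.testing.assert_array_equal(Z[:, 1], 0.0)  # centred, not scaled

    def test_transform_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        scaler = Standardizer.fit(X)
        v = rng.normal(size=(1, 3))
        np.testing.assert_array_equal(scaler.transform(v), scaler.transform(v))


class TestRBFKernel:
    def test_self_similarity_is_one(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 0.5) == 1.0

    def test_distance_delta_gives_inverse_e(self):
        assert rbf_kernel([0.0], [2.0], 2.0) == pytest.approx(np.exp(-1))

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, z = rng.normal(size=(2, 6))
            assert rbf_kernel(x, z, 1.3) == pytest.approx(
                rbf_kernel(z, x, 1.3), abs=1e-15)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0], 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0, 2.0], 1.0)


class TestSolveDual:
    def test_separable_pair_classified(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([-1.0, 1.0])
        model = solve_dual(X, y, C=10.0, delta=1.0)
        assert predict(model, X).tolist() == [-1, 1]

    @pytest.mark.parametrize("seed,n", [(0, 3), (1, 3), (2, 4), (3, 4)])
    def test_matches_brute_force_qp(self, seed, n):
        """Dual objective agrees with an independent QP solve to 1e-4."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = np.r_[np.ones(n - n // 2), -np.ones(n // 2)]
        C, delta = 5.0, 1.5
        model = solve_dual(X, y, C=C, delta=delta, tol=1e-6)
        obj_oracle, _ = qp_oracle(X, y, C, delta)
        assert model.dual_objective == pytest.approx(obj_oracle, abs=1e-4)

    def test_near_linear_kernel_against_oracle(self):
        """With a very wide kernel the dual still matches the QP oracle."""
        X = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 1.5]])
        y = np.array([-1.0, -1.0, 1.0])
        C, delta = 3.0, 50.0
        model = solve_dual(X, y, C=C, delta=delta, tol=1e-8)
        obj_oracle, _ = qp_oracle(X, y, C, delta)
        assert model.dual_objective == pytest.approx(obj_oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_feasibility_of_converged_models(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 4))
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        X[y > 0] += 1.0
        C = 2.0
        model = solve_dual(X, y, C=C, delta=2.0, tol=1e-5)
        assert abs(np.sum(model.support_alphas * model.support_labels)) < 1e-8
        assert np.all(model.support_alphas >= -1e-9)
        assert np.all(model.support_alphas <= C + 1e-9)
        assert model.converged and model.kkt_gap < 1e-5

    def test_matches_sklearn_reference(self):
        """Independent cross-check: objective and bias agree with libsvm."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 5))
        y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        X[y > 0] += 1.0
        C, delta = 10.0, 2.0
        model = solve_dual(X, y, C=C, delta=delta, tol=1e-5)
        sk = SVC(C=C, gamma=1.0 / delta ** 2, kernel="rbf", tol=1e-7).fit(X, y)
        alpha = np.zeros(40)
        alpha[sk.support_] = np.abs(sk.dual_coef_[0])
        K = rbf_kernel_matrix(X, X, delta)
        ay = alpha * y
        sk_obj = alpha.sum() - 0.5 * ay @ K @ ay
        assert model.dual_objective == pytest.approx(sk_obj, abs=1e-3)
        assert model.bias == pytest.approx(sk.intercept_[0], abs=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            solve_dual(np.zeros((3, 1)), np.ones(3), C=1.0, delta=1.0)

    def test_invalid_penalty_rejected(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        with pytest.raises(ValueError):
            solve_dual(X, y, C=0.0, delta=1.0)

    def test_margin_monotonicity_in_C(self):
        """Growing C buys less slack: total hinge slack is non-increasing,
        and on near-separable data the training error falls to zero."""
        rng = np.random.default_rng(4)
        X = np.r_[rng.normal(0.0, 1.0, size=(30, 2)),
                  rng.normal(1.5, 1.0, size=(30, 2))]
        y = np.r_[-np.ones(30), np.ones(30)]
        slacks = []
        for C in (0.01, 0.1, 1.0, 10.0, 100.0):
            model = solve_dual(X, y, C=C, delta=2.0, tol=1e-8,
                               max_iter=500_000)
            f = decision_function(model, X)
            slacks.append(float(np.maximum(0.0, 1.0 - y * f).sum()))
        assert np.all(np.diff(slacks) <= 1e-6)

        rng = np.random.default_rng(2)
        X = np.r_[rng.normal(0.0, 0.7, size=(20, 2)),
                  rng.normal(2.5, 0.7, size=(20, 2))]
        y = np.r_[-np.ones(20), np.ones(20)]
        errors = []
        for C in (0.01, 0.1, 1.0, 10.0, 100.0):
            model = solve_dual(X, y, C=C, delta=2.0, tol=1e-8,
                               max_iter=500_000)
            errors.append(int(np.sum(predict(model, X) != y)))
        assert np.all(np.diff(errors) <= 0)
        assert errors[-1] == 0


class TestPredict:
    def test_training_labels_recovered_on_separable_set(self):
        rng = np.random.default_rng(5)
        X = np.r_[rng.normal(-2.0, 0.3, size=(10, 2)),
                  rng.normal(2.0, 0.3, size=(10, 2))]
        y = np.r_[-np.ones(10), np.ones(10)]
        model = solve_dual(X, y, C=10.0, delta=2.0)
        assert predict(model, X).tolist() == y.tolist()

    def test_far_point_takes_bias_sign(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = solve_dual(X, y, C=10.0, delta=0.5)
        far = np.array([[1e4]])
        f = decision_function(model, far)
        assert f[0] == pytest.approx(model.bias)
        assert predict(model, far)[0] == (1 if model.bias >= 0 else -1)

    def test_invariant_to_splitting_support_vector(self):
        """Duplicating a support vector with alpha halved leaves f unchanged."""
        from dataclasses import replace

        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 2))
        y = np.r_[np.ones(6), -np.ones(6)]
        X[:6] += 1.5
        model = solve_dual(X, y, C=5.0, delta=1.5)
        split = replace(
            model,
            support_vectors=np.r_[model.support_vectors,
                                  model.support_vectors[:1]],
            support_alphas=np.r_[model.support_alphas[0] / 2,
                                 model.support_alphas[1:],
                                 model.support_alphas[0] / 2],
            support_labels=np.r_[model.support_labels,
                                 model.support_labels[:1]],
        )
        probe = rng.normal(size=(20, 2))
        np.testing.assert_allclose(decision_function(split, probe),
                                   decision_function(model, probe),
                                   atol=1e-12)

    def test_length_mismatch_rejected(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = solve_dual(X, y, C=1.0, delta=1.0)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 3)))


class TestGridSearch:
    def test_grid_dimensions(self):
        assert len(C_EXPONENTS) == 41
        assert len(DELTA_EXPONENTS) == 41
        assert C_EXPONENTS[0] == -5.0 and C_EXPONENTS[-1] == 15.0
        assert DELTA_EXPONENTS[0] == -15.0 and DELTA_EXPONENTS[-1] == 5.0
        assert np.allclose(np.diff(C_EXPONENTS), 0.5)

    def test_separable_data_reaches_full_accuracy(self):
        rng = np.random.default_rng(7)
        X = np.r_[rng.normal(-3.0, 0.3, size=(20, 2)),
                  rng.normal(3.0, 0.3, size=(20, 2))]
        y = np.r_[-np.ones(20), np.ones(20)]
        res = grid_search(X, y, folds=5, seed=0,
                          C_grid=2.0 ** np.arange(-2.0, 8.0),
                          delta_grid=2.0 ** np.arange(-2.0, 6.0))
        assert res.best_accuracy == 1.0

    def test_same_seed_identical_surface(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 3))
        y = np.r_[np.ones(12), -np.ones(12)]
        X[:12] += 1.0
        grids = dict(C_grid=2.0 ** np.arange(0.0, 3.0),
                     delta_grid=2.0 ** np.arange(-1.0, 2.0))
        a = grid_search(X, y, folds=4, seed=3, **grids)
        b = grid_search(X, y, folds=4, seed=3, **grids)
        np.testing.assert_array_equal(a.cv_accuracy, b.cv_accuracy)
        assert (a.best_C, a.best_delta) == (b.best_C, b.best_delta)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((3, 2)), np.array([1.0, -1.0, 1.0]), folds=5)


class TestStratifiedSplit:
    def test_study_allocation(self):
        """73 males and 60 females split 70/30 into 93 train / 40 test."""
        y = np.r_[np.ones(73), -np.ones(60)]
        train, test = stratified_split(y, 0.7, seed=0)
        assert len(train) == 93 and len(test) == 40
        assert np.sum(y[train] == 1) == 51 and np.sum(y[train] == -1) == 42
        assert np.sum(y[test] == 1) == 22 and np.sum(y[test] == -1) == 18

    def test_half_split(self):
        y = np.r_[np.ones(10), -np.ones(10)]
        train, test = stratified_split(y, 0.5, seed=1)
        assert len(train) == 10
        assert np.sum(y[train] == 1) == 5

    def test_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(9)
        y = np.where(rng.random(37) < 0.4, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        train, test = stratified_split(y, 0.7, seed=2)
        combined = np.sort(np.r_[train, test])
        np.testing.assert_array_equal(combined, np.arange(37))

    def test_tiny_class_rejected(self):
        y = np.array([1.0, -1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            stratified_split(y, 0.7, seed=0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([1.0, -1.0]), 1.0, seed=0)


class TestEvaluation:
    def test_printed_confusion_rates(self):
        """20/22 correct males -> 90.9%; 17/18 correct females -> 94.4%."""
        report = EvalReport(male_tested=22, male_correct=20,
                            female_tested=18, female_correct=17)
        assert report.male_rate == 90.9
        assert report.female_rate == 94.4
        assert report.male_misjudged == 2
        assert report.female_misjudged == 1

    def test_all_correct_rates(self):
        report = EvalReport(10, 10, 8, 8)
        assert report.male_rate == 100.0
        assert report.female_rate == 100.0

    def test_rate_rounding(self):
        assert correct_rate(20, 22) == 90.9
        assert correct_rate(17, 18) == 94.4
        assert correct_rate(1, 3) == 33.3

    def test_evaluate_counts_from_model(self):
        rng = np.random.default_rng(10)
        X = np.r_[rng.normal(-2.0, 0.3, size=(12, 2)),
                  rng.normal(2.0, 0.3, size=(12, 2))]
        y = np.r_[-np.ones(12), np.ones(12)]
        model = solve_dual(X, y, C=10.0, delta=2.0)
        report = evaluate(model, X, y)
        assert report.male_tested == 12 and report.female_tested == 12
        assert report.male_tested == report.male_correct + report.male_misjudged
        assert report.male_rate == 100.0 and report.female_rate == 100.0

    def test_empty_test_set_rejected(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = solve_dual(X, y, C=1.0, delta=1.0)
        with pytest.raises(ValueError):
            evaluate(model, np.empty((0, 1)), np.empty(0))
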