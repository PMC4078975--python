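import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from cellsift import (DataError, auc, fit_logistic, predict,
                      wilcoxon_signed_rank)
from cellsift.learning import (_logistic_objective, evaluate_protocol,
                               l1_logistic_path)
from cellsift.synthetic import make_enrichment_table
from cellsift.tasks import TaskSpec, build_task

from _oracles import pairwise_auc, wilcoxon_exact_by_enumeration


def toy_problem(rng, n=40, p=6, informative=0):
    X = rng.standard_normal((n, p))
    y = np.sign(X[:, informative] + 0.3 * rng.standard_normal(n)).astype(int)
    y[y == 0] = 1
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return X, y


class TestFitLogistic:
    def test_l1_fully_penalized_limit(self, rng):
        X, y = toy_problem(rng)
        m = fit_logistic(X, y, 1e7, "l1")
        assert np.all(m.w == 0.0)
        n_pos, n_neg = (y == 1).sum(), (y == -1).sum()
        assert m.b == pytest.approx(np.log(n_pos / n_neg), abs=1e-3)

    def test_l2_separable_toy(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        m = fit_logistic(X, y, 0.01, "l2")
        assert m.w[0] > 0
        assert auc(predict(m, X), y) == 1.0

    def test_l2_gradient_vanishes_at_optimum(self, rng):
        X, y = toy_problem(rng, n=30, p=4)
        lam = 0.5
        m = fit_logistic(X, y, lam, "l2", tol=1e-10)
        theta = np.append(m.w, m.b)
        # independent finite-difference gradient oracle
        eps = 1e-6
        fd = np.empty_like(theta)
        for i in range(len(theta)):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            fu, _ = _logistic_objective(up, X, y.astype(float), lam)
            fd_, _ = _logistic_objective(dn, X, y.astype(float), lam)
            fd[i] = (fu - fd_) / (2 * eps)
        assert np.linalg.norm(fd) < 1e-4

    def test_l2_optimum_beats_origin_and_random_points(self, rng):
        X, y = toy_problem(rng)
        lam = 1.0
        m = fit_logistic(X, y, lam, "l2")
        f_opt, _ = _logistic_objective(np.append(m.w, m.b), X, y.astype(float), lam)
        f_zero, _ = _logistic_objective(np.zeros(X.shape[1] + 1), X,
                                        y.astype(float), lam)
        assert f_opt <= f_zero + 1e-9
        for _ in range(5):
            theta = rng.standard_normal(X.shape[1] + 1)
            f_rand, _ = _logistic_objective(theta, X, y.astype(float), lam)
            assert f_opt <= f_rand + 1e-9

    def test_l1_sparsity_monotone_in_lambda(self, rng):
        X, y = toy_problem(rng, n=60, p=10)
        grid = np.geomspace(20.0, 0.01, 12)
        thetas = l1_logistic_path(X, y, grid)
        nnz = [(np.abs(t[:-1]) > 1e-8).sum() for t in thetas]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_single_class_rejected(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(DataError):
            fit_logistic(X, np.ones(5), 1.0)

    def test_nonfinite_features_rejected(self):
        X = np.array([[np.nan], [1.0]])
        from cellsift import ValidationError
        with pytest.raises(ValidationError):
            fit_logistic(X, np.array([-1, 1]), 1.0)


class TestPredict:
    def test_zero_model_gives_zero_scores(self, rng):
        from cellsift.learning import Model
        m = Model(np.zeros(3), 0.0)
        assert np.all(predict(m, rng.random((4, 3))) == 0.0)

    def test_affine_consistency(self, rng):
        from cellsift.learning import Model
        X = rng.random((6, 3))
        m = Model(rng.random(3), 0.4)
        half = Model(m.w / 2, 0.4)
        assert np.allclose(predict(half, 2 * X), predict(m, X))

    def test_hand_computed_example(self):
        from cellsift.learning import Model
        m = Model(np.array([2.0, -1.0]), 0.5)
        X = np.array([[1.0, 3.0]])
        assert predict(m, X)[0] == pytest.approx(2.0 - 3.0 + 0.5)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, -1], [1, 1, 1, -1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.3] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_derived_half_example(self):
        scores = np.array([0.9, 0.4, 0.35, 0.8])
        y = np.array([1, -1, 1, -1])
        assert auc(scores, y) == 0.5
        assert pairwise_auc(scores, y) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = rng.choice([0.1, 0.2, 0.5, 0.9], size=n)   # forces ties
        y = rng.choice([-1, 1], size=n)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        assert auc(scores, y) == pytest.approx(pairwise_auc(scores, y))

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(12)
        y = np.array([1] * 6 + [-1] * 6)
        assert auc(scores, y) == pytest.approx(auc(np.exp(2 * scores) + 3, y))


class TestEvaluateProtocol:
    def make_dataset(self, n_genes=24, p=4, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        X = rng.standard_normal((n_genes, p))
        pos = X[:, 0] > 0
        if pos.sum() < 2 or (~pos).sum() < 2:
            pos[:2] = [True, False]
        table = make_enrichment_table(
            [(g, "neuron", 5.0) for g, is_pos in zip(genes, pos) if is_pos])
        import pandas as pd
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
        frame.insert(0, "gene_id", genes)
        return build_task(table, TaskSpec("N-vs-Neg", 1.5), frame)

    def test_deterministic_given_seed(self):
        ds = self.make_dataset()
        r1 = evaluate_protocol(ds, n_reps=3, seed=5)
        r2 = evaluate_protocol(ds, n_reps=3, seed=5)
        assert np.array_equal(r1.aucs, r2.aucs)
        assert np.array_equal(r1.lambdas, r2.lambdas)

    def test_report_length_and_range(self):
        ds = self.make_dataset()
        report = evaluate_protocol(ds, n_reps=4, seed=1)
        assert len(report.aucs) == 4
        assert np.all((report.aucs >= 0) & (report.aucs <= 1))
        summary = report.summary()
        assert summary["min"] <= summary["median"] <= summary["max"]


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank(a, a)
        assert res.p_value == 1.0

    def test_symmetry(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
            wilcoxon_signed_rank(b, a).p_value)

    def test_six_positive_differences_exact(self):
        b = np.zeros(6)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.statistic == 21.0
        assert res.p_value == pytest.approx(2.0 / 64.0)
        w_obs, p_oracle = wilcoxon_exact_by_enumeration(a - b)
        assert res.statistic == w_obs
        assert res.p_value == pytest.approx(p_oracle)

    @given(st.integers(0, 2**31 - 1))
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = rng.choice([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0], size=n)  # ties in |d|
        res = wilcoxon_signed_rank(d, np.zeros(n))
        w_obs, p_oracle = wilcoxon_exact_by_enumeration(d)
        assert res.statistic == pytest.approx(w_obs)
        assert res.p_value == pytest.approx(p_oracle)

    def test_normal_approximation_matches_scipy(self, rng):
        a = rng.standard_normal(40) + 0.3
        b = rng.standard_normal(40)
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "normal"
        ref = scipy_wilcoxon(a, b, zero_method="wilcox", correction=True,
                             method="approx", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)
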