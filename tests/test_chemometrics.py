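"""NIPALS PCA against the SVD oracle; polynomial regression and LOO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from quincarb import chemometrics as C


def svd_oracle(Xc, k):
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    frac = s[:k] ** 2 / np.sum(Xc * Xc)
    return scores, loadings, frac


class TestMeanCenter:
    def test_column_means_zero(self, rng):
        X = rng.normal(5, 2, (8, 4))
        Xc, means = C.mean_center(X)
        assert np.allclose(Xc.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(X, Xc + means)

    def test_constant_column_zeroed(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        Xc, means = C.mean_center(X)
        assert np.allclose(Xc[:, 0], 0)
        assert means[0] == pytest.approx(3.0)

    def test_idempotent(self, rng):
        Xc, _ = C.mean_center(rng.normal(size=(6, 3)))
        Xcc, means = C.mean_center(Xc)
        assert np.allclose(Xcc, Xc) and np.allclose(means, 0, atol=1e-12)


class TestNipals:
    def test_rank_one_matrix_fully_explained(self):
        t = np.array([1.0, 2.0, -1.0, 3.0, 0.5])
        p = np.array([0.5, -1.0, 2.0, 0.3])
        Xc, _ = C.mean_center(np.outer(t, p))
        model = C.nipals_pca(Xc, 1)
        assert model.explained[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("shape", [(6, 4), (10, 8), (20, 50)])
    def test_matches_svd_oracle(self, shape, rng):
        Xc, _ = C.mean_center(rng.normal(size=shape))
        k = min(shape[0] - 1, shape[1], 4)
        model = C.nipals_pca(Xc, k)
        scores, loadings, frac = svd_oracle(Xc, k)
        for j in range(k):
            sign = np.sign(np.dot(model.loadings[:, j], loadings[:, j]))
            assert np.allclose(model.scores[:, j], sign * scores[:, j], atol=1e-6)
            assert np.allclose(model.loadings[:, j], sign * loadings[:, j], atol=1e-6)
        assert np.allclose(model.explained, frac, atol=1e-8)

    def test_score_orthogonality_and_unit_loadings(self, rng):
        Xc, _ = C.mean_center(rng.normal(size=(12, 7)))
        model = C.nipals_pca(Xc, 4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))
        assert np.allclose(np.linalg.norm(model.loadings, axis=0), 1.0)

    def test_reconstruction_error_non_increasing(self, rng):
        Xc, _ = C.mean_center(rng.normal(size=(10, 6)))
        errors = []
        for k in range(1, 6):
            m = C.nipals_pca(Xc, k)
            errors.append(np.sum((Xc - m.scores @ m.loadings.T) ** 2))
        assert np.all(np.diff(errors) <= 1e-9)

    def test_full_rank_fractions_sum_to_one(self, rng):
        Xc, _ = C.mean_center(rng.normal(size=(7, 4)))
        model = C.nipals_pca(Xc, 4)  # rank after centering <= min(n-1, p) = 4
        assert model.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_component_count_validation(self, rng):
        Xc, _ = C.mean_center(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            C.nipals_pca(Xc, 5)

    def test_explained_variance_arithmetic(self):
        model = C.PCAModel(
            scores=np.column_stack([np.array([3.0, 0, 0]), np.array([0, np.sqrt(3), 0])]),
            loadings=np.eye(3)[:, :2], explained=np.array([0.75, 0.25]),
            column_means=np.zeros(3),
        )
        out = C.explained_variance(model, total_ss=12.0)
        assert np.allclose(out[:, 0], [0.75, 0.25])
        assert out[-1, 1] == pytest.approx(1.0)


class TestPolynomialDesign:
    @pytest.mark.parametrize(
        "k,degree,n_terms", [(2, 1, 3), (2, 3, 10), (1, 5, 6), (3, 2, 10)]
    )
    def test_term_counts(self, k, degree, n_terms, rng):
        X, terms = C.polynomial_design(rng.normal(size=(7, k)), degree)
        assert X.shape[1] == len(terms) == n_terms
        assert n_terms == math.comb(degree + k, k)

    def test_degree_one_columns(self, rng):
        S = rng.normal(size=(5, 2))
        X, terms = C.polynomial_design(S, 1)
        assert terms == [(0, 0), (1, 0), (0, 1)]
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(X[:, 1], S[:, 0]) and np.allclose(X[:, 2], S[:, 1])

    def test_univariate_powers(self):
        s = np.array([1.0, 2.0, -1.0])
        X, terms = C.polynomial_design(s, 5)
        assert np.allclose(X, np.column_stack([s**i for i in range(6)]))

    def test_degree_validation(self, rng):
        with pytest.raises(ValueError):
            C.polynomial_design(rng.normal(size=(4, 1)), 6)
        X, _ = C.polynomial_design(rng.normal(size=(9, 1)), 7, allow_any_degree=True)
        assert X.shape[1] == 8


class TestRegression:
    def test_exact_linear_recovery(self):
        s = np.array([-2.0, -1, 0, 1, 2])
        y = 2 + 3 * s
        X, terms = C.polynomial_design(s, 1)
        m = C.fit_regression(X, y, terms=terms, degree=1)
        assert np.allclose(m.coefficients, [2.0, 3.0], atol=1e-12)
        assert m.r_squared == pytest.approx(1.0)
        assert m.se_regression == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        B_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        m = C.fit_regression(X, y)
        assert np.allclose(m.coefficients, B_oracle, atol=1e-8)

    def test_mean_only_model(self, rng):
        y = rng.normal(size=6)
        m = C.fit_regression(np.ones((6, 1)), y)
        assert m.coefficients[0] == pytest.approx(y.mean())

    def test_rank_deficient_warns_minimum_norm(self, rng):
        x = rng.normal(size=6)
        X = np.column_stack([x, 2 * x, np.ones(6)])
        with pytest.warns(RuntimeWarning):
            m = C.fit_regression(X, rng.normal(size=6))
        assert np.all(np.isfinite(m.coefficients))

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            C.fit_regression(rng.normal(size=(3, 3)), rng.normal(size=3))

    def test_training_sse_non_increasing_in_degree(self, rng):
        s = rng.normal(size=12)
        y = rng.normal(size=12)
        sse = []
        for d in (1, 2, 3, 4, 5):
            X, terms = C.polynomial_design(s, d)
            m = C.fit_regression(X, y, terms=terms, degree=d)
            resid = y - X @ m.coefficients
            sse.append(resid @ resid)
        assert np.all(np.diff(sse) <= 1e-9)


class TestLooCV:
    def test_exact_linear_interpolation(self):
        s = np.linspace(-2, 2, 8)
        y = 1.0 - 0.5 * s
        rep = C.loo_cv(s, y, 1)
        assert rep.cv_mse == pytest.approx(0.0, abs=1e-18)
        assert rep.q2 == pytest.approx(1.0)
        assert rep.avg_r2_loo == pytest.approx(1.0)

    def test_brute_force_fold_oracle(self):
        s = np.array([-2.0, -1, 0, 1, 2])
        y = np.array([-2.0, -1, 0, 1, 4])
        rep = C.loo_cv(s, y, 1)
        for i in range(5):
            mask = np.arange(5) != i
            A = np.column_stack([np.ones(4), s[mask]])
            b = np.linalg.solve(A.T @ A, A.T @ y[mask])
            assert rep.loo_predictions[i] == pytest.approx(b[0] + b[1] * s[i])

    def test_q2_not_above_r2_under_noise(self, rng):
        # holding out data cannot systematically beat the training fit
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            s = r.normal(size=15)
            y = 0.8 * s + r.normal(scale=0.5, size=15)
            X, terms = C.polynomial_design(s, 1)
            m = C.fit_regression(X, y, terms=terms, degree=1)
            rep = C.loo_cv(s, y, 1)
            hits += rep.q2 <= m.r_squared
        assert hits >= 95


class TestSelectModel:
    def test_linear_data_ties_to_degree_one(self, rng):
        s = rng.normal(size=(12, 2))
        y = 1 + s[:, 0] - 2 * s[:, 1]
        model, rep = C.select_model(s, y, degrees=(1, 2, 3))
        assert model.degree == 1

    def test_admissibility_guard(self, rng):
        # n=13, k=2: degree 4 has 15 terms > 11 and must never be a candidate
        assert C.admissible_degrees(13, 2, (1, 2, 3, 4, 5)) == [1, 2, 3]
        s = rng.normal(size=(8, 2))
        with pytest.raises(ValueError):
            C.select_model(s, rng.normal(size=8), degrees=(4, 5))

    def test_planted_cubic_recovered_modally(self):
        # degree-3 truth, 10% response noise, n=40: modal selected degree is 3
        from quincarb.synthetic import FingerprintTruth, generate_fingerprints

        selected = []
        for seed in range(20):
            X, y, truth = generate_fingerprints(
                n_compounds=40, truth=FingerprintTruth(seed=seed)
            )
            Xc, _ = C.mean_center(X.to_numpy())
            pca = C.nipals_pca(Xc, 2)
            model, _ = C.select_model(pca.scores, y.to_numpy(), degrees=(1, 2, 3, 4, 5))
            selected.append(model.degree)
        values, counts = np.unique(selected, return_counts=True)
        assert values[np.argmax(counts)] == 3
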