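"""NIPALS principal component analysis and polynomial regression with
leave-one-out cross-validation.

The bioactivity model works in two stages.  A compound x energy-variable
matrix X (rows = compounds) is mean-centred by column and decomposed by the
NIPALS algorithm into rank-1 terms X = sum_i t_i p_i^T (scores t, unit-norm
loadings p, sequential deflation) — PCA on the covariance matrix, no column
scaling.  The retained scores then feed a multivariate polynomial
regression: the design matrix holds every monomial in the scores up to a
total degree (1..5), the coefficient matrix is B = (X^T X)^-1 X^T Y solved
through a rank-tolerant pseudo-inverse, and candidate degrees are compared
by leave-one-out cross-validation, selecting the degree with the smallest
mean squared prediction error.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "PCAModel",
    "PolynomialModel",
    "CVReport",
    "mean_center",
    "nipals_pca",
    "explained_variance",
    "polynomial_design",
    "monomial_exponents",
    "fit_regression",
    "loo_cv",
    "select_model",
]


@dataclass
class PCAModel:
    """Scores/loadings/explained-variance triplet from NIPALS.

    ``scores`` is n x r (columns t_i), ``loadings`` p x r (unit-norm columns
    p_i), ``explained`` the per-component fraction of the centred matrix's
    total sum of squares, ``column_means`` the centering vector, and
    ``iterations`` the NIPALS iteration count per component (-1 flags a
    component that hit ``max_iter`` without converging).
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray
    column_means: np.ndarray
    iterations: List[int] = field(default_factory=list)

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)


@dataclass
class PolynomialModel:
    degree: int
    terms: List[Tuple[int, ...]]  # monomial exponents over the scores
    coefficients: np.ndarray
    r_squared: float
    se_regression: float  # response units, n - #terms dof


@dataclass
class CVReport:
    loo_predictions: np.ndarray  # one held-out prediction per row
    cv_mse: float
    avg_r2_loo: float  # mean training R^2 over the folds
    q2: float  # 1 - PRESS/TSS

    @property
    def press(self) -> float:
        return float(self.cv_mse * len(self.loo_predictions))


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("data matrix must be 2-D with >= 2 rows and columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix must be finite")
    return X


def mean_center(X) -> Tuple[np.ndarray, np.ndarray]:
    """Column mean-centre; returns the centred matrix and the means."""
    X = _as_2d(X)
    means = X.mean(axis=0)
    return X - means, means


def nipals_pca(
    Xc, n_components: int, tol: float = 1e-9, max_iter: int = 1000
) -> PCAModel:
    """Sequential NIPALS extraction of principal components with deflation.

    Each component is a power iteration on the residual matrix: starting
    from the column of largest variance, alternate p = X^T t / t^T t
    (normalised) and t = X p until the relative change of the score vector
    drops to ``tol``.  After extraction the rank-1 term t p^T is deflated.
    The sign of each component is fixed so the largest-magnitude loading
    element is positive.  Deterministic — no randomness anywhere.
    """
    X = _as_2d(Xc).copy()
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}] for a {n}x{p} matrix"
        )
    total_ss = float(np.sum(X * X))
    if total_ss == 0:
        raise ValueError("centred matrix has zero total sum of squares")
    scores = np.empty((n, n_components))
    loadings = np.empty((p, n_components))
    explained = np.empty(n_components)
    iterations: List[int] = []
    for comp in range(n_components):
        start = int(np.argmax(np.sum(X * X, axis=0)))
        t = X[:, start].copy()
        if np.allclose(t, 0):  # residual exhausted: component is null
            t = np.ones(n)
        n_iter = -1
        for it in range(1, max_iter + 1):
            pv = X.T @ t / float(t @ t)
            pv /= np.linalg.norm(pv)
            t_new = X @ pv
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= tol * max(np.linalg.norm(t), np.finfo(float).tiny):
                n_iter = it
                break
        if n_iter == -1:
            warnings.warn(
                f"NIPALS component {comp + 1} did not converge in {max_iter} "
                "iterations", RuntimeWarning,
            )
        # sign convention: largest-|loading| element positive
        pivot = int(np.argmax(np.abs(pv)))
        if pv[pivot] < 0:
            pv, t = -pv, -t
        scores[:, comp] = t
        loadings[:, comp] = pv
        explained[comp] = float(t @ t) / total_ss
        iterations.append(n_iter)
        X -= np.outer(t, pv)
    return PCAModel(
        scores=scores, loadings=loadings, explained=explained,
        column_means=np.zeros(p), iterations=iterations,
    )


def explained_variance(model: PCAModel, total_ss: float | None = None) -> np.ndarray:
    """Per-component and cumulative variance fractions.

    ``total_ss`` rescales the fractions to a different total sum of squares
    (e.g. of the uncentred residual); by default the model's own fractions
    are returned.  Returns an array of shape (r, 2): fraction, cumulative.
    """
    if total_ss is not None:
        if not total_ss > 0:
            raise ValueError("total_ss must be positive")
        comp_ss = np.sum(model.scores**2, axis=0)
        frac = comp_ss / total_ss
    else:
        frac = np.asarray(model.explained, dtype=float)
    return np.column_stack([frac, np.cumsum(frac)])


def monomial_exponents(n_vars: int, degree: int) -> List[Tuple[int, ...]]:
    """Exponent tuples of all monomials with total degree <= degree,
    in graded lexicographic order (intercept first)."""
    terms: List[Tuple[int, ...]] = []
    for total in range(degree + 1):
        layer = [
            e for e in itertools.product(range(total + 1), repeat=n_vars)
            if sum(e) == total
        ]
        terms.extend(sorted(layer, reverse=True))
    return terms


def polynomial_design(
    scores, degree: int, allow_any_degree: bool = False
) -> Tuple[np.ndarray, List[Tuple[int, ...]]]:
    """Design matrix of all monomials in the score columns up to ``degree``.

    Includes the intercept and every cross term; column count is
    C(degree + k, k) for k score variables.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if not allow_any_degree and not 1 <= degree <= 5:
        raise ValueError("degree must be in 1..5")
    if degree < 0:
        raise ValueError("degree must be non-negative")
    terms = monomial_exponents(S.shape[1], degree)
    cols = [np.prod(S**np.array(e), axis=1) for e in terms]
    return np.column_stack(cols), terms


def fit_regression(
    design, Y, terms: Sequence[Tuple[int, ...]] | None = None,
    degree: int | None = None, rcond: float = 1e-12,
) -> PolynomialModel:
    """Least-squares coefficients B = (X^T X)^-1 X^T Y via pseudo-inverse.

    Solved through SVD with singular values below ``rcond`` times the
    largest treated as zero, which reduces to the normal-equations solution
    at full rank and the minimum-norm solution otherwise (with a warning).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(Y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("design and response lengths differ")
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need >= {k + 1} rows to fit {k} coefficients")
    rank = np.linalg.matrix_rank(X, tol=rcond * np.abs(X).max())
    if rank < k:
        warnings.warn("rank-deficient design; returning the minimum-norm solution",
                      RuntimeWarning)
    B, *_ = np.linalg.lstsq(X, y, rcond=rcond)
    resid = y - X @ B
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    df = n - k
    se = float(np.sqrt(ss_res / df)) if df > 0 else 0.0
    return PolynomialModel(
        degree=degree if degree is not None else max(sum(t) for t in terms) if terms else -1,
        terms=list(terms) if terms is not None else [],
        coefficients=B, r_squared=max(0.0, min(1.0, r2)), se_regression=se,
    )


def loo_cv(scores, Y, degree: int) -> CVReport:
    """Leave-one-out cross-validation of the polynomial regression.

    Each row is held out in turn, the regression is refitted on the rest and
    the held-out response predicted.  Reports the mean squared prediction
    error, q2 = 1 - PRESS/TSS, and the mean of the fold training R^2 values
    ("average R^2 in LOO" — a training-side diagnostic, deliberately
    reported separately from the predictive q2).
    """
    X, terms = polynomial_design(scores, degree)
    y = np.asarray(Y, dtype=float).ravel()
    n, k = X.shape
    if n < k + 2:
        raise ValueError("too few rows for leave-one-out at this degree")
    preds = np.empty(n)
    fold_r2 = np.empty(n)
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        mask = np.arange(n) != i
        Xi, yi = X[mask], y[mask]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                m = fit_regression(Xi, yi, terms=terms, degree=degree)
        except (RuntimeWarning, ValueError):
            warnings.warn(f"LOO fold {i} rank-deficient; excluded from cv_mse",
                          RuntimeWarning)
            ok[i] = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_regression(Xi, yi, terms=terms, degree=degree)
        preds[i] = float(X[i] @ m.coefficients)
        fold_r2[i] = m.r_squared
    press = float(np.sum((y[ok] - preds[ok]) ** 2))
    cv_mse = press / int(ok.sum())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - float(np.sum((y - preds) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return CVReport(
        loo_predictions=preds, cv_mse=cv_mse,
        avg_r2_loo=float(fold_r2[ok].mean()), q2=q2,
    )


def admissible_degrees(n: int, n_vars: int, degrees: Sequence[int]) -> List[int]:
    """Degrees whose full monomial basis keeps #terms <= n - 2."""
    return [d for d in degrees if math.comb(d + n_vars, n_vars) <= n - 2]


def select_model(
    scores, Y, degrees: Sequence[int] = (1, 2, 3, 4, 5)
) -> Tuple[PolynomialModel, CVReport]:
    """Pick the polynomial degree minimising the LOO mean squared error.

    Saturated fits are excluded by the admissibility guard #terms <= n - 2;
    ties go to the lower degree.  Returns the model refitted on all rows
    together with its cross-validation report.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n, k = S.shape
    cand = admissible_degrees(n, k, sorted(set(degrees)))
    if not cand:
        raise ValueError("no admissible polynomial degree for this sample size")
    best = None
    for d in cand:
        report = loo_cv(S, Y, d)
        if best is None or report.cv_mse < best[1].cv_mse - 1e-15:
            X, terms = polynomial_design(S, d)
            model = fit_regression(X, Y, terms=terms, degree=d)
            best = (model, report)
    return best
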