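"""Alternative dimension-reduction front-ends for benchmarking.

PCA, truncated SVD, regularized LDA and L1 (lasso) feature selection all
expose the same ``fit(X, y) / transform(X)`` contract as the kernel-PCA
front-end, so the comparison harness can swap them blindly ahead of the
same classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.linear_model import LogisticRegression

from . import kpca as _kpca


@dataclass(frozen=True)
class ReducerSpec:
    """Which front-end to use and its parameters."""

    method: str = "kpca"
    n_components: int | str = "auto"
    variance_fraction: float = 0.3
    kernel: _kpca.KernelSpec = dc_field(default_factory=_kpca.KernelSpec)
    lasso_lambda: float | None = None  # None -> internal CV over a log grid
    center_svd: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kpca", "pca", "svd", "lda", "lasso"):
            raise ValueError(f"unknown reduction method {self.method!r}")


class KpcaReducer:
    def __init__(self, spec: _kpca.KernelSpec = _kpca.KernelSpec(),
                 n_components: int | str = "auto", variance_fraction: float = 0.3):
        self.spec = spec
        self.n_components = n_components
        self.variance_fraction = variance_fraction
        self.model_: _kpca.KpcaModel | None = None

    def fit(self, X, y=None):
        self.model_ = _kpca.fit_kpca(X, self.spec, self.n_components,
                                     self.variance_fraction)
        return self

    def transform(self, X):
        return _kpca.transform(self.model_, X)


class PcaReducer:
    """Center, eigendecompose the covariance, project on top-k eigenvectors."""

    def __init__(self, n_components: int | str = "auto", variance_fraction: float = 0.3):
        self.n_components = n_components
        self.variance_fraction = variance_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        k = self.n_components
        if k == "auto":
            full = PCA().fit(X)
            k = _k_for_fraction(full.explained_variance_, self.variance_fraction)
            k = max(1, min(int(k), X.shape[0] - 1, X.shape[1]))
        elif not 1 <= int(k) <= min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(f"n_components {k} out of range for shape {X.shape}")
        self._pca = PCA(n_components=k, svd_solver="full").fit(X)
        return self

    def transform(self, X):
        return self._pca.transform(np.asarray(X, dtype=float))

    def inverse_transform(self, Z):
        return self._pca.inverse_transform(Z)


class SvdReducer:
    """Project on the top-k right singular vectors of the (by default
    uncentered) data matrix."""

    def __init__(self, n_components: int | str = "auto",
                 variance_fraction: float = 0.3, center: bool = False, seed: int = 0):
        self.n_components = n_components
        self.variance_fraction = variance_fraction
        self.center = center
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self._mean = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        Xc = X - self._mean
        k = self.n_components
        if k == "auto":
            s = scipy.linalg.svdvals(Xc)
            k = _k_for_fraction(s**2, self.variance_fraction)
            k = max(1, min(int(k), min(Xc.shape) - 1))
        elif not 1 <= int(k) <= min(Xc.shape) - 1:
            raise ValueError(f"n_components {k} out of range for shape {Xc.shape}")
        self._svd = TruncatedSVD(n_components=k, random_state=self.seed).fit(Xc)
        return self

    def transform(self, X):
        return self._svd.transform(np.asarray(X, dtype=float) - self._mean)


class LdaReducer:
    """Fisher discriminant directions from the generalized eigenproblem
    ``S_b v = lambda S_w v``.

    On large-p / small-n data the within-class scatter is singular, so it
    is ridge-regularized by ``ridge * trace(S_w)/p`` on the diagonal.
    At most C-1 components exist for C classes.
    """

    def __init__(self, n_components: int | None = None, ridge: float = 1e-6):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        C = len(classes)
        k = self.n_components if self.n_components is not None else C - 1
        if k > C - 1:
            raise ValueError(
                f"LDA rank bound: at most C-1={C - 1} components for {C} classes, got {k}"
            )
        p = X.shape[1]
        grand = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        for c in classes:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            d = Xc - mu
            Sw += d.T @ d
            m = (mu - grand)[:, None]
            Sb += len(Xc) * (m @ m.T)
        Sw += np.eye(p) * self.ridge * (np.trace(Sw) / p if np.trace(Sw) > 0 else 1.0)
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
        order = np.argsort(evals)[::-1][:k]
        W = evecs[:, order]
        # deterministic sign
        flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
        flip[flip == 0] = 1.0
        self.scalings_ = W * flip[None, :]
        self._mean = grand
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self._mean) @ self.scalings_


class LassoSelector:
    """L1-penalized one-vs-rest logistic models as a feature filter.

    A feature is selected if any class's coefficient is nonzero; the
    transform restricts the matrix to selected columns.  ``lam`` is the
    penalty strength (inverse of sklearn's C); ``lam=None`` picks it by
    internal stratified CV over a log grid.
    """

    LAM_GRID = np.logspace(-3, 2, 11)

    def __init__(self, lam: float | None = None, seed: int = 0, cv: int = 3):
        if lam is not None and lam < 0:
            raise ValueError("lambda must be >= 0")
        self.lam = lam
        self.seed = seed
        self.cv = cv

    def _fit_ovr(self, X, y, lam):
        C = 1.0 / max(lam, 1e-12)
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000,
            random_state=self.seed,
        )
        classes = np.unique(y)
        coefs = []
        for c in classes:
            clf.fit(X, (y == c).astype(int))
            coefs.append(clf.coef_.ravel())
        return np.vstack(coefs)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        lam = self.lam
        if lam is None:
            lam = self._select_lambda(X, y)
        coefs = self._fit_ovr(X, y, lam)
        self.lambda_ = float(lam)
        self.selected_ = np.flatnonzero(np.any(coefs != 0, axis=0))
        if self.selected_.size == 0:
            raise ValueError(
                f"lambda={lam:g} shrank every coefficient to zero; use a smaller lambda"
            )
        return self

    def _select_lambda(self, X, y):
        from .evaluation import stratified_kfold

        folds = stratified_kfold(y, min(self.cv, np.bincount(y).min()), self.seed)
        best_lam, best_score = self.LAM_GRID[0], -np.inf
        for lam in self.LAM_GRID:
            scores = []
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
                coefs = self._fit_ovr(X[train_idx], y[train_idx], lam)
                sel = np.flatnonzero(np.any(coefs != 0, axis=0))
                if sel.size == 0:
                    scores.append(0.0)
                    continue
                clf = LogisticRegression(max_iter=2000, random_state=self.seed)
                clf.fit(X[train_idx][:, sel], y[train_idx])
                scores.append(clf.score(X[test_idx][:, sel], y[test_idx]))
            score = float(np.mean(scores))
            if score > best_score:
                best_lam, best_score = lam, score
        return best_lam

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.selected_]


def fit_pca(X, k: int | str = "auto", variance_fraction: float = 0.3) -> PcaReducer:
    return PcaReducer(k, variance_fraction).fit(X)


def fit_svd(X, k: int | str = "auto", variance_fraction: float = 0.3,
            center: bool = False) -> SvdReducer:
    return SvdReducer(k, variance_fraction, center).fit(X)


def fit_lda(X, y, k: int | None = None, ridge: float = 1e-6) -> LdaReducer:
    return LdaReducer(k, ridge).fit(X, y)


def fit_lasso_select(X, y, lam: float | None = None, seed: int = 0) -> LassoSelector:
    return LassoSelector(lam, seed).fit(X, y)


def make_reducer(spec: ReducerSpec):
    """Instantiate the reducer named by ``spec`` (unfitted)."""
    if spec.method == "kpca":
        return KpcaReducer(spec.kernel, spec.n_components, spec.variance_fraction)
    if spec.method == "pca":
        return PcaReducer(spec.n_components, spec.variance_fraction)
    if spec.method == "svd":
        return SvdReducer(spec.n_components, spec.variance_fraction,
                          spec.center_svd, spec.seed)
    if spec.method == "lda":
        k = None if spec.n_components == "auto" else int(spec.n_components)
        return LdaReducer(k)
    return LassoSelector(spec.lasso_lambda, spec.seed)


def _k_for_fraction(variances: np.ndarray, fraction: float) -> int:
    v = np.asarray(variances, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        return 1
    shares = np.cumsum(v) / v.sum()
    return int(np.searchsorted(shares, fraction - 1e-12) + 1)
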