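"""Kernel principal components analysis with out-of-sample projection.

Kernel PCA performs PCA in the implicit feature space of a kernel
``K(x, x')`` by eigendecomposing the double-centered Gram matrix of the
training set.  For the RBF kernel

    K(x, x') = exp(-gamma * ||x - x'||^2)

the similarity lies in (0, 1] and decreases with distance; ``gamma``
defaults to the reciprocal of the feature count.  New points are projected
through the cross-kernel against the retained training points, centered
with the stored training statistics — required so that fold-wise fitting
never touches test data.

A grid search over kernel kind and gamma, scored by downstream
cross-validated classification accuracy, selects the kernel configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

KERNEL_KINDS = ("linear", "rbf", "poly", "sigmoid")

#: Relative eigenvalue cutoff: components with eigenvalue below this times
#: the largest eigenvalue are treated as numerically zero.
EIG_RTOL = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind plus hyper-parameters.

    ``gamma=None`` means the field-standard default 1/#features, resolved
    at fit time.  ``degree``/``coef0`` apply to poly (and coef0 to sigmoid).
    """

    kind: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected {KERNEL_KINDS}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


def rbf_kernel(x: np.ndarray, x2: np.ndarray, gamma: float) -> float:
    """exp(-gamma * squared Euclidean distance) between two vectors."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {x2.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    d = x - x2
    return float(np.exp(-gamma * np.dot(d, d)))


def _pairwise_sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xx = np.sum(X * X, axis=1)[:, None]
    yy = np.sum(Y * Y, axis=1)[None, :]
    d2 = xx + yy - 2.0 * (X @ Y.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def cross_kernel(Xnew: np.ndarray, Xtrain: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel values between every row of ``Xnew`` and every row of ``Xtrain``."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    Xtrain = np.atleast_2d(np.asarray(Xtrain, dtype=float))
    if Xnew.shape[1] != Xtrain.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {Xnew.shape[1]} vs {Xtrain.shape[1]}"
        )
    g = spec.resolve_gamma(Xtrain.shape[1])
    if spec.kind == "linear":
        return Xnew @ Xtrain.T
    if spec.kind == "rbf":
        return np.exp(-g * _pairwise_sq_dists(Xnew, Xtrain))
    if spec.kind == "poly":
        return (g * (Xnew @ Xtrain.T) + spec.coef0) ** spec.degree
    # sigmoid
    return np.tanh(g * (Xnew @ Xtrain.T) + spec.coef0)


def kernel_matrix(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Symmetric Gram matrix of ``X`` under ``spec``."""
    G = cross_kernel(X, X, spec)
    return 0.5 * (G + G.T)  # enforce exact symmetry against roundoff


def center_kernel(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Double-center a Gram matrix (feature-space mean removal).

    Returns ``(centered, row_means, grand_mean)``; the statistics are needed
    to center cross-kernels of unseen points consistently.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("Gram matrix must be square")
    row_means = G.mean(axis=1)
    grand_mean = float(G.mean())
    centered = G - row_means[:, None] - row_means[None, :] + grand_mean
    return centered, row_means, grand_mean


def center_cross(Gcross: np.ndarray, row_means: np.ndarray, grand_mean: float) -> np.ndarray:
    """Center a cross-kernel block with stored training statistics."""
    Gcross = np.asarray(Gcross, dtype=float)
    return (
        Gcross
        - Gcross.mean(axis=1, keepdims=True)
        - row_means[None, :]
        + grand_mean
    )


@dataclass
class KpcaModel:
    """Fitted kernel-PCA transform.

    ``components`` has shape (n_train, m) with eigenvector columns scaled by
    1/sqrt(eigenvalue); a projection is ``centered_cross_kernel @ components``.
    """

    spec: KernelSpec
    train_points: np.ndarray
    row_means: np.ndarray
    grand_mean: float
    eigenvalues: np.ndarray  # non-increasing, all > 0
    components: np.ndarray
    train_scores: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def fit_kpca(X: np.ndarray, spec: KernelSpec = KernelSpec(),
             n_components: int | str = "auto",
             variance_fraction: float = 0.3) -> KpcaModel:
    """Fit kernel PCA on ``X``.

    ``n_components="auto"`` keeps the smallest number of components whose
    eigenvalues cover ``variance_fraction`` of the positive spectrum; an
    integer asks for that many (clipped, with a warning, to the number of
    positive eigenvalues).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    G = kernel_matrix(X, spec)
    Gc, row_means, grand_mean = center_kernel(G)
    evals, evecs = np.linalg.eigh(Gc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = EIG_RTOL * max(evals[0], 0.0)
    n_pos = int(np.sum(evals > max(tol, 0.0)))
    if n_pos == 0:
        raise ValueError("degenerate kernel: no positive eigenvalues")
    if n_components == "auto":
        k = select_components(evals[:n_pos], variance_fraction=variance_fraction)
    else:
        k = int(n_components)
        if k > n_pos:
            warnings.warn(
                f"requested {k} components but only {n_pos} positive eigenvalues; clipped",
                stacklevel=2,
            )
            k = n_pos
        if k < 1:
            raise ValueError("n_components must be >= 1")
    evals, evecs = evals[:k], evecs[:, :k]
    # deterministic sign: largest-magnitude coefficient of each component positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    components = evecs / np.sqrt(evals)[None, :]
    train_scores = Gc @ components  # == evecs * sqrt(evals)
    return KpcaModel(spec, X.copy(), row_means, grand_mean, evals, components, train_scores)


def transform(model: KpcaModel, Xnew: np.ndarray) -> np.ndarray:
    """Project new points onto the fitted kernel principal components."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.train_points.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {Xnew.shape[1]} vs {model.train_points.shape[1]}"
        )
    Gcross = cross_kernel(Xnew, model.train_points, model.spec)
    Gc = center_cross(Gcross, model.row_means, model.grand_mean)
    return Gc @ model.components


def select_components(eigenvalues: Sequence[float], *,
                      fixed_k: int | None = None,
                      variance_fraction: float = 0.3) -> int:
    """Number of components to retain.

    Fixed-k policy returns ``min(fixed_k, #positive eigenvalues)``; otherwise
    the smallest k whose cumulative eigenvalue share reaches
    ``variance_fraction``.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    tol = EIG_RTOL * max(float(ev[0]), 0.0)
    pos = ev[ev > tol]
    if pos.size == 0:
        raise ValueError("degenerate kernel: all eigenvalues are zero")
    if fixed_k is not None:
        if fixed_k < 1:
            raise ValueError("fixed_k must be >= 1")
        return min(int(fixed_k), pos.size)
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must lie in (0, 1]")
    shares = np.cumsum(pos) / pos.sum()
    return int(np.searchsorted(shares, variance_fraction - 1e-12) + 1)


@dataclass
class GridSearchResult:
    """Outcome of the exhaustive kernel/gamma search."""

    best: KernelSpec
    table: list[tuple[KernelSpec, float]]


DEFAULT_GAMMA_GRID = (0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06)


def grid_search(ds, kernels: Sequence[str] = KERNEL_KINDS,
                gammas: Sequence[float] = DEFAULT_GAMMA_GRID,
                classifier_factory: Callable | None = None,
                n_splits: int = 4, seed: int = 0,
                n_components: int | str = "auto") -> GridSearchResult:
    """Exhaustively score every kernel x gamma candidate by mean CV accuracy.

    Each candidate reduces the training folds with kernel PCA and scores the
    downstream classifier (default: a reduced-budget cascade forest) on the
    held-out folds.  Gamma is ignored for the linear kernel, which appears
    once.  Ties break by grid order.
    """
    from .cascade import CascadeConfig, CascadeForestClassifier
    from .evaluation import stratified_kfold

    if not list(kernels) or not list(gammas):
        raise ValueError("empty parameter grid")
    if classifier_factory is None:
        def classifier_factory():  # small budget: search tractability
            return CascadeForestClassifier(
                CascadeConfig(n_trees=10, max_layers=2, seed=seed)
            )

    candidates: list[KernelSpec] = []
    for kind in kernels:
        if kind == "linear":
            candidates.append(KernelSpec(kind="linear"))
        else:
            candidates.extend(KernelSpec(kind=kind, gamma=g) for g in gammas)

    X, y = ds.X, ds.y
    plan = stratified_kfold(y, n_splits, seed)
    table: list[tuple[KernelSpec, float]] = []
    for spec in candidates:
        accs = []
        for test_idx in plan:
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            try:
                model = fit_kpca(X[train_idx], spec, n_components=n_components)
            except ValueError:  # degenerate kernel on this fold
                accs.append(0.0)
                continue
            clf = classifier_factory()
            clf.fit(transform(model, X[train_idx]), y[train_idx])
            pred = clf.predict(transform(model, X[test_idx]))
            accs.append(float(np.mean(pred == y[test_idx])))
        table.append((spec, float(np.mean(accs))))
        logger.debug("grid candidate %s -> %.4f", spec, table[-1][1])
    best = max(table, key=lambda t: t[1])[0]  # max is stable: first maximal wins
    return GridSearchResult(best=best, table=table)
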