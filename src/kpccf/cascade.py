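"""Cascade (deep) forest with class-vector augmentation and adaptive depth.

Each cascade layer holds four forests — two random forests (bootstrap,
sqrt(p) feature subsampling, Gini splits) and two completely-random tree
forests (each split picks a feature uniformly at random and a threshold
uniformly at random within that feature's observed range, growing until
leaves are label-pure).  Every forest emits a class-probability vector per
sample; the four vectors (4*C values for C classes) are concatenated with
the layer's input features to form the next layer's input.  Depth adapts:
layers are added until validation accuracy plateaus, a target accuracy is
reached, or a hard cap, and the model is truncated at the best layer.

Training-time class vectors are generated out-of-fold (stratified internal
splits) so that augmented features are honest estimates rather than the
near-one-hot vectors a purity-grown forest produces on its own training
points; a ``resubstitution`` flag restores the literal
fit-and-score-on-train variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

FOREST_KINDS = ("random", "completely_random")


@dataclass(frozen=True)
class ForestSpec:
    kind: str = "random"
    n_trees: int = 30
    seed: int = 0
    split_mode: str = "uniform"  # completely_random only: uniform | gini

    def __post_init__(self) -> None:
        if self.kind not in FOREST_KINDS:
            raise ValueError(f"unknown forest kind {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.split_mode not in ("uniform", "gini"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")


# ---------------------------------------------------------------------------
# Completely-random trees


class CompletelyRandomTree:
    """Decision tree whose splits are chosen without looking at the labels.

    At each node a feature is drawn uniformly among features that vary
    there, and the threshold uniformly between the feature's min and max at
    the node (``split_mode="gini"`` instead scans cut points of the random
    feature for the best Gini impurity decrease).  Growth stops when the
    node is label-pure or no feature varies; leaves store the empirical
    class distribution.
    """

    def __init__(self, n_classes: int, seed: int = 0, split_mode: str = "uniform"):
        self.n_classes = n_classes
        self.seed = seed
        self.split_mode = split_mode
        # flat node arrays; children index -1 marks a leaf
        self._feature: list[int] = []
        self._threshold: list[float] = []
        self._left: list[int] = []
        self._right: list[int] = []
        self._dist: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CompletelyRandomTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) < 1:
            raise ValueError("need at least 1 sample")
        rng = np.random.default_rng(self.seed)
        self._new_node()
        stack = [(0, np.arange(len(y)))]
        while stack:
            node, idx = stack.pop()
            labels = y[idx]
            counts = np.bincount(labels, minlength=self.n_classes)
            if np.count_nonzero(counts) <= 1:  # pure
                self._make_leaf(node, counts)
                continue
            Xn = X[idx]
            lo, hi = Xn.min(axis=0), Xn.max(axis=0)
            varying = np.flatnonzero(hi > lo)
            if varying.size == 0:  # constant features, mixed labels
                self._make_leaf(node, counts)
                continue
            f = int(rng.choice(varying))
            if self.split_mode == "uniform":
                t = float(rng.uniform(lo[f], hi[f]))
                if t >= hi[f]:  # guard the measure-zero edge
                    t = float(lo[f])
            else:
                t = self._best_gini_threshold(Xn[:, f], labels)
            mask = Xn[:, f] <= t
            if mask.all() or not mask.any():  # threshold at boundary
                t = float(lo[f])
                mask = Xn[:, f] <= t
            self._feature[node] = f
            self._threshold[node] = t
            self._left[node] = self._new_node()
            self._right[node] = self._new_node()
            stack.append((self._left[node], idx[mask]))
            stack.append((self._right[node], idx[~mask]))
        return self

    def _best_gini_threshold(self, x: np.ndarray, labels: np.ndarray) -> float:
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], labels[order]
        cuts = np.flatnonzero(np.diff(xs) > 0)
        onehot = np.eye(self.n_classes)[ys]
        left = np.cumsum(onehot, axis=0)[cuts]
        total = onehot.sum(axis=0)
        nl = left.sum(axis=1)
        nr = len(ys) - nl
        gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum(((total - left) / nr[:, None]) ** 2, axis=1)
        score = (nl * gini_l + nr * gini_r) / len(ys)
        best = int(np.argmin(score))
        return float(0.5 * (xs[cuts[best]] + xs[cuts[best] + 1]))

    def _new_node(self) -> int:
        self._feature.append(-1)
        self._threshold.append(np.nan)
        self._left.append(-1)
        self._right.append(-1)
        self._dist.append(None)  # type: ignore[arg-type]
        return len(self._feature) - 1

    def _make_leaf(self, node: int, counts: np.ndarray) -> None:
        self._dist[node] = counts / counts.sum()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), self.n_classes))
        # breadth-wise traversal: push index sets down the tree
        pending = [(0, np.arange(len(X)))]
        while pending:
            node, idx = pending.pop()
            if idx.size == 0:
                continue
            if self._left[node] == -1:
                out[idx] = self._dist[node]
                continue
            mask = X[idx, self._feature[node]] <= self._threshold[node]
            pending.append((self._left[node], idx[mask]))
            pending.append((self._right[node], idx[~mask]))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class CompletelyRandomForest:
    """Average of ``n_trees`` completely-random trees fitted on the full sample."""

    def __init__(self, spec: ForestSpec, n_classes: int):
        self.spec = spec
        self.n_classes = n_classes
        self.trees: list[CompletelyRandomTree] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CompletelyRandomForest":
        seeds = np.random.SeedSequence(self.spec.seed).generate_state(self.spec.n_trees)
        self.trees = [
            CompletelyRandomTree(self.n_classes, int(s) % (2**31), self.spec.split_mode).fit(X, y)
            for s in seeds
        ]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = np.zeros((np.atleast_2d(X).shape[0], self.n_classes))
        for t in self.trees:
            proba += t.predict_proba(X)
        return proba / len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class _SklearnForest:
    """Random forest (bootstrap + sqrt(p) features + Gini) with fixed-width
    class-probability output even when a training fold misses a class."""

    def __init__(self, spec: ForestSpec, n_classes: int):
        self.spec = spec
        self.n_classes = n_classes
        self._rf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            random_state=spec.seed,
        )

    def fit(self, X, y):
        self._rf.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        proba = self._rf.predict_proba(np.atleast_2d(X))
        out = np.zeros((proba.shape[0], self.n_classes))
        out[:, self._rf.classes_.astype(int)] = proba
        return out

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def fit_tree_completely_random(X: np.ndarray, y: np.ndarray, seed: int = 0,
                               split_mode: str = "uniform") -> CompletelyRandomTree:
    """Grow a single completely-random tree to leaf purity."""
    y = np.asarray(y, dtype=int)
    return CompletelyRandomTree(int(y.max()) + 1, seed, split_mode).fit(X, y)


def fit_forest(X: np.ndarray, y: np.ndarray, spec: ForestSpec,
               n_classes: int | None = None):
    """Fit one forest of either kind; returns an object with ``predict_proba``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to fit a forest")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    cls = CompletelyRandomForest if spec.kind == "completely_random" else _SklearnForest
    return cls(spec, n_classes).fit(X, y)


# ---------------------------------------------------------------------------
# Cascade


@dataclass(frozen=True)
class CascadeConfig:
    n_trees: int = 30
    max_layers: int = 10
    patience: int = 1
    target_accuracy: float | None = None
    n_splits: int = 3
    seed: int = 0
    resubstitution: bool = False
    split_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")


#: fixed forest order within a layer: 2 random + 2 completely-random
LAYER_KINDS = ("random", "random", "completely_random", "completely_random")


@dataclass
class CascadeLayer:
    forests: list
    oof_class_vectors: np.ndarray  # (n, 4*C)
    validation_accuracy: float


@dataclass
class CascadeModel:
    layers: list[CascadeLayer]
    n_classes: int
    input_dim: int
    termination: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _layer_specs(config: CascadeConfig, layer_seed: np.random.SeedSequence) -> list[ForestSpec]:
    seeds = layer_seed.generate_state(len(LAYER_KINDS))
    return [
        ForestSpec(kind=k, n_trees=config.n_trees, seed=int(s) % (2**31),
                   split_mode=config.split_mode)
        for k, s in zip(LAYER_KINDS, seeds)
    ]


def _stratified_splits(y: np.ndarray, n_splits: int, seed: int) -> list[np.ndarray]:
    from .evaluation import stratified_kfold

    return stratified_kfold(y, n_splits, seed)


def layer_oof_class_vectors(X: np.ndarray, y: np.ndarray, specs: list[ForestSpec],
                            n_classes: int, n_splits: int = 3, seed: int = 0,
                            resubstitution: bool = False) -> np.ndarray:
    """Per-forest class-probability blocks, concatenated in forest order.

    Each sample's vector comes from a forest trained on internal stratified
    folds not containing it (unless ``resubstitution``).  Classes smaller
    than ``n_splits`` make stratification impossible and raise.
    """
    n = len(y)
    counts = np.bincount(y, minlength=n_classes)
    present = np.flatnonzero(counts)
    if not resubstitution and counts[present].min() < n_splits:
        small = int(present[np.argmin(counts[present])])
        raise ValueError(
            f"class {small} has {counts[small]} members < n_splits={n_splits}: "
            "stratified out-of-fold class vectors impossible; reduce n_splits "
            "or use resubstitution"
        )
    block = np.empty((n, len(specs) * n_classes))
    for fi, spec in enumerate(specs):
        cols = slice(fi * n_classes, (fi + 1) * n_classes)
        if resubstitution:
            forest = fit_forest(X, y, spec, n_classes)
            block[:, cols] = forest.predict_proba(X)
            continue
        folds = _stratified_splits(y, n_splits, seed)
        fold_seeds = np.random.SeedSequence(spec.seed).generate_state(n_splits)
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            sub = ForestSpec(spec.kind, spec.n_trees, int(fold_seeds[k]) % (2**31),
                             spec.split_mode)
            forest = fit_forest(X[train_idx], y[train_idx], sub, n_classes)
            block[test_idx, cols] = forest.predict_proba(X[test_idx])
    return block


def fit_cascade(X: np.ndarray, y: np.ndarray,
                config: CascadeConfig = CascadeConfig()) -> CascadeModel:
    """Grow the cascade layer by layer with adaptive depth.

    Layer 1 trains on ``X``; layer t>1 on ``[X || previous layer's class
    vectors]``.  Per-layer validation accuracy comes from the out-of-fold
    vectors.  Stops on plateau (``patience`` layers without improvement),
    on reaching ``target_accuracy``, or at ``max_layers``; the returned
    model is truncated at the best-scoring layer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n_classes = int(y.max()) + 1
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    root = np.random.SeedSequence(config.seed)
    layer_seeds = root.spawn(config.max_layers)

    layers: list[CascadeLayer] = []
    accs: list[float] = []
    stop_reason = "max_layers"
    A = X
    for t in range(config.max_layers):
        specs = _layer_specs(config, layer_seeds[t])
        oof_seed = int(layer_seeds[t].generate_state(1)[0]) % (2**31)
        block = layer_oof_class_vectors(
            A, y, specs, n_classes, config.n_splits, oof_seed, config.resubstitution
        )
        mean_proba = block.reshape(len(y), len(specs), n_classes).mean(axis=1)
        acc = float(np.mean(np.argmax(mean_proba, axis=1) == y))
        forests = [fit_forest(A, y, s, n_classes) for s in specs]
        layers.append(CascadeLayer(forests, block, acc))
        accs.append(acc)
        logger.debug("layer %d validation accuracy %.4f", t + 1, acc)
        if config.target_accuracy is not None and acc >= config.target_accuracy:
            stop_reason = "target_reached"
            break
        best_so_far = int(np.argmax(accs))
        if t - best_so_far >= config.patience:
            stop_reason = "plateau"
            break
        A = np.hstack([X, block])
    best = int(np.argmax(accs))
    model = CascadeModel(
        layers=layers[: best + 1],
        n_classes=n_classes,
        input_dim=X.shape[1],
        termination={
            "stop_reason": stop_reason,
            "layer_accuracies": accs,
            "best_layer": best + 1,
            "best_accuracy": accs[best],
        },
    )
    return model


def predict_proba(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Propagate through the layers; final probability = mean of the last
    layer's four forest vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"feature dimension mismatch: {X.shape[1]} vs {model.input_dim}")
    A = X
    block = None
    for layer in model.layers:
        block = np.hstack([f.predict_proba(A) for f in layer.forests])
        A = np.hstack([X, block])
    C = model.n_classes
    return block.reshape(len(X), -1, C).mean(axis=1)


def predict(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Class labels; ties break toward the lowest class index."""
    return np.argmax(predict_proba(model, X), axis=1)


class CascadeForestClassifier:
    """Thin estimator-style wrapper (fit / predict / predict_proba)."""

    def __init__(self, config: CascadeConfig = CascadeConfig()):
        self.config = config
        self.model_: CascadeModel | None = None

    def fit(self, X, y):
        self.model_ = fit_cascade(X, y, self.config)
        return self

    def predict(self, X):
        return predict(self.model_, X)

    def predict_proba(self, X):
        return predict_proba(self.model_, X)
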