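"""The end-to-end KPCCF estimator: kernel-PCA reduction into a cascade forest.

Fitting first reduces the training matrix with kernel PCA (default: RBF
kernel, gamma = 0.05, components chosen to cover 30% of the positive
eigenvalue mass) and then grows the adaptive-depth cascade forest on the
reduced features.  Prediction projects new samples through the stored
kernel transform — centered with training-set statistics only, so
fold-wise evaluation is leak-free — and propagates them through the
cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import joblib
import numpy as np

from . import cascade as _cascade
from . import kpca as _kpca
from .taxa_io import LabeledDataset

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class KpccfConfig:
    """Configuration snapshot for the full estimator."""

    kernel: _kpca.KernelSpec = field(
        default_factory=lambda: _kpca.KernelSpec(kind="rbf", gamma=0.05)
    )
    n_components: int | str = "auto"
    variance_fraction: float = 0.3
    cascade: _cascade.CascadeConfig = field(default_factory=_cascade.CascadeConfig)
    grid_search: bool = False
    seed: int = 0

    def reseeded(self, seed: int) -> "KpccfConfig":
        return replace(self, seed=seed,
                       cascade=replace(self.cascade, seed=seed))


@dataclass
class KpccfModel:
    kpca: _kpca.KpcaModel
    cascade: _cascade.CascadeModel
    config: KpccfConfig
    class_names: list[str]


def fit_kpccf(train: LabeledDataset, config: KpccfConfig = KpccfConfig()) -> KpccfModel:
    """Fit kernel PCA on the training split, then the cascade on reduced features."""
    X, y = train.X, train.y
    if len(np.unique(y)) < 2:
        raise ValueError("kpccf: need at least 2 classes")
    kernel = config.kernel
    if config.grid_search:
        result = _kpca.grid_search(train, seed=config.seed,
                                   n_components=config.n_components)
        kernel = result.best
    try:
        kmodel = _kpca.fit_kpca(X, kernel, config.n_components, config.variance_fraction)
    except ValueError as e:
        raise ValueError(f"kpccf feature-reduction stage: {e}") from e
    try:
        cmodel = _cascade.fit_cascade(kmodel.train_scores, y, config.cascade)
    except ValueError as e:
        raise ValueError(f"kpccf cascade stage: {e}") from e
    return KpccfModel(kmodel, cmodel, config, list(train.class_names))


def predict_proba_kpccf(model: KpccfModel, X: np.ndarray) -> np.ndarray:
    Z = _kpca.transform(model.kpca, X)
    return _cascade.predict_proba(model.cascade, Z)


def predict_kpccf(model: KpccfModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (as class-name strings) and class-probability rows."""
    proba = predict_proba_kpccf(model, X)
    idx = np.argmax(proba, axis=1)
    labels = np.array([model.class_names[i] for i in idx])
    return labels, proba


class KpccfClassifier:
    """Estimator-style wrapper over :func:`fit_kpccf` for the CV harness."""

    def __init__(self, config: KpccfConfig = KpccfConfig()):
        self.config = config
        self.model_: KpccfModel | None = None

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        names = [f"class_{c}" for c in range(int(y.max()) + 1)]
        from .taxa_io import SampleFeatureMatrix

        mat = SampleFeatureMatrix(
            [f"i{i}" for i in range(len(y))],
            [f"f{j}" for j in range(np.atleast_2d(X).shape[1])],
            np.atleast_2d(np.asarray(X, float)),
        )
        ds = LabeledDataset(mat, [names[c] for c in y], names)
        self.model_ = fit_kpccf(ds, self.config)
        return self

    def predict(self, X):
        return np.argmax(predict_proba_kpccf(self.model_, X), axis=1)

    def predict_proba(self, X):
        return predict_proba_kpccf(self.model_, X)


def save_model(model: KpccfModel, path) -> None:
    joblib.dump({"version": SERIALIZATION_VERSION, "model": model}, path)


def load_model(path) -> KpccfModel:
    payload = joblib.load(path)
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model container version {payload.get('version')!r}")
    return payload["model"]
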