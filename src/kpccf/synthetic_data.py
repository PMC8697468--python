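"""Deterministic generators for microbiome-like benchmark data.

Real taxon-abundance tables in the small-n / large-p case-control setting
are sparse non-negative count matrices with heavy-tailed magnitudes and
imbalanced multi-class labels.  The generators here emulate those surface
properties while planting a known low-dimensional class structure:

``linear``
    classes are shifted Gaussian clouds in latent space (separable by a
    hyperplane);
``concentric``
    classes live on nested radial shells in latent space, so no hyperplane
    separates them in the raw coordinates but a radial (RBF-style) kernel
    can — the discriminating fixture for the kernel front-end;
``none``
    no class signal at all (null data for calibration checks).

Latent points are embedded into ``n_features`` dimensions by a seeded
random linear map, pushed through an exponential to heavy-tailed
log-normal magnitudes, rounded to counts, and thinned to the target zero
fraction.  Rounding supplies structure-correlated zeros (low abundance
drops out, as in real tables); a Bernoulli mask adds the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .taxa_io import (
    LabeledDataset,
    OtuTable,
    SampleFeatureMatrix,
    TaxonomyLineage,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``sparsity`` is the target fraction of exact zeros; ``noise_scale`` the
    latent within-class spread (shell thickness for ``concentric``);
    ``class_proportions`` default to a mildly imbalanced split.
    """

    n_samples: int = 200
    n_features: int = 40
    n_classes: int = 3
    sparsity: float = 0.5
    structure: str = "concentric"
    class_proportions: tuple[float, ...] | None = None
    noise_scale: float = 0.1
    seed: int = 0
    latent_dim: int = 3
    count_scale: float = 0.7  # log-scale slope of the count magnitudes
    mean_calibration: float = 0.5  # 0 = raw log-normal, 1 = fully mean-flattened

    def __post_init__(self) -> None:
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.structure not in ("linear", "concentric", "none"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        props = self.class_proportions
        if props is None:
            # imbalance peaking at the middle class: for concentric
            # structure the middle shell is the one no hyperplane can carve
            # out, so weighting it keeps the fixture linearly inseparable
            c = np.arange(self.n_classes)
            raw = np.minimum(c + 1, self.n_classes - c).astype(float)
            props = tuple(raw / raw.sum())
            object.__setattr__(self, "class_proportions", props)
        if len(props) != self.n_classes or not np.isclose(sum(props), 1.0):
            raise ValueError("class_proportions must sum to 1, one per class")

    @property
    def majority_rate(self) -> float:
        return max(self.class_proportions)


def _class_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.array(spec.class_proportions) * spec.n_samples).astype(int)
    counts = np.maximum(counts, 1)
    # distribute the remainder to the largest classes
    for i in np.argsort(counts)[::-1]:
        if counts.sum() >= spec.n_samples:
            break
        counts[i] += spec.n_samples - counts.sum()
    while counts.sum() > spec.n_samples:
        counts[np.argmax(counts)] -= 1
    y = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(y)
    return y


def _latent(spec: SyntheticSpec, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, d = spec.n_samples, spec.latent_dim
    if spec.structure == "none":
        return rng.normal(size=(n, d))
    if spec.structure == "linear":
        sep = 2.0
        means = rng.normal(size=(spec.n_classes, d))
        means *= sep / np.linalg.norm(means, axis=1, keepdims=True)
        return means[y] + rng.normal(scale=0.5 + spec.noise_scale, size=(n, d))
    # concentric: class c sits on a shell of radius 1 + c
    dirs = rng.normal(size=(n, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = 1.0 + y + rng.normal(scale=spec.noise_scale, size=n)
    return dirs * radii[:, None]


def _to_counts(embedded: np.ndarray, latent: np.ndarray, W: np.ndarray,
               spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Rounded log-normal magnitudes with partial mean calibration and
    Bernoulli thinning.

    Counts are ``round(exp(loc + a))`` with ``a`` the scaled embedded
    latent value minus ``mean_calibration`` times the log of its
    conditional expected magnitude (a function of the sample's latent norm
    and the feature's loading).  The exponential map is convex, so without
    calibration the expected abundance grows with the latent norm and a
    concentric dataset becomes ordinally separable by total abundance —
    a hyperplane reads the shell radius off the first moments.  Full
    calibration over-corrects: it rescales each sample by its radius and
    re-creates an ordinal signal in the zero pattern.  The half-weight
    default damps first-moment separability below useful levels while
    preserving the graded nonlinear geometry the kernel needs.

    ``loc`` is set so that rounding alone produces 60% of the target zeros
    (structure-correlated, like genuinely absent taxa); random Bernoulli
    thinning supplies the rest.
    """
    a = spec.count_scale * embedded
    # E[exp(s * w.z)] = exp(s^2 ||z||^2 |w|^2 / (2 d)) for z on a shell
    w_norms = np.sum(W * W, axis=0)
    r2 = np.sum(latent * latent, axis=1)
    a -= (spec.mean_calibration * 0.5 * spec.count_scale**2
          * np.outer(r2, w_norms) / spec.latent_dim)
    loc = float(np.log(0.5) - np.quantile(a, 0.6 * spec.sparsity))
    counts = np.round(np.exp(loc + a))
    if spec.sparsity > 0:
        p_nat = float(np.mean(counts == 0))
        if p_nat < spec.sparsity:
            t = (spec.sparsity - p_nat) / (1.0 - p_nat)
            counts[rng.random(counts.shape) < t] = 0
    return counts


def generate_labeled(spec: SyntheticSpec) -> LabeledDataset:
    """Labeled sample-feature count dataset with planted class structure."""
    rng = np.random.default_rng(spec.seed)
    y = _class_labels(spec, rng)
    z = _latent(spec, y, rng)
    W = rng.normal(size=(spec.latent_dim, spec.n_features)) / np.sqrt(spec.latent_dim)
    counts = _to_counts(z @ W, z, W, spec, rng)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    feature_names = [f"taxon_{j:03d}" for j in range(spec.n_features)]
    class_names = [f"class_{c}" for c in range(spec.n_classes)]
    mat = SampleFeatureMatrix(sample_ids, feature_names, counts)
    return LabeledDataset(mat, [class_names[c] for c in y], class_names)


# ---------------------------------------------------------------------------
# OTU-table fixtures


def generate_otu_fixture(spec: SyntheticSpec, n_families: int = 5,
                         otus_per_family: int = 4,
                         n_truncated: int = 0) -> OtuTable:
    """Sparse OTU table whose lineages carry full rank prefixes.

    OTUs are spread evenly over ``n_families`` families, each with a
    distinct genus per member OTU.  ``n_truncated`` extra OTUs get lineages
    cut off above family rank, to exercise unclassified handling.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    n_otus = n_families * otus_per_family + n_truncated
    rng = np.random.default_rng(spec.seed)
    counts = np.round(
        np.exp(rng.normal(loc=0.0, scale=1.0, size=(n_otus, spec.n_samples)))
    )
    counts[rng.random(counts.shape) < spec.sparsity] = 0
    lineages: list[TaxonomyLineage] = []
    phyla = ("Firmicutes", "Bacteroidetes", "Proteobacteria")
    for i in range(n_families * otus_per_family):
        fam = i // otus_per_family
        lineages.append(TaxonomyLineage({
            "k": "Bacteria",
            "p": phyla[fam % len(phyla)],
            "c": f"Class{fam % 2}",
            "o": f"Order{fam}",
            "f": f"Family{fam:02d}",
            "g": f"Genus{fam:02d}_{i % otus_per_family}",
        }))
    for j in range(n_truncated):
        lineages.append(TaxonomyLineage({
            "k": "Bacteria", "p": phyla[j % len(phyla)],
        }))
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    return OtuTable(lineages, sample_ids, counts.astype(np.int64))


def generate_metadata(sample_ids: Sequence[str], labels: Sequence[str],
                      seed: int = 0, missing_rate: float = 0.0) -> pd.DataFrame:
    """Metadata table (DiseaseState + age + gender) aligned to sample ids."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    age = np.round(rng.normal(50, 12, size=n)).astype(float)
    gender = rng.choice(["M", "F"], size=n)
    meta = pd.DataFrame(
        {"DiseaseState": list(labels), "age": age, "gender": gender},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if missing_rate > 0:
        mask = rng.random(n) < missing_rate
        meta.loc[mask, "age"] = np.nan
    return meta
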