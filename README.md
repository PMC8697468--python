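# kpccf

Kernel-PCA feature reduction feeding an adaptively deep cascade forest —
a classification toolkit for sparse, small-n / large-p microbiome
abundance tables.

Case-control 16S studies produce OTU count tables with hundreds of taxa
and a few dozen to a few hundred subjects, most entries exactly zero.
Predicting a multi-class disease state from such tables is a "large p,
small n" problem in which deep neural networks overfit and raw-feature
ensembles inherit noise.  KPCCF first lifts the counts through kernel
PCA — eigendecomposition of the double-centered Gram matrix of
`K(x, x') = exp(−γ‖x − x′‖²)` — to a small number of nonlinear
components, then classifies with a cascade forest: layers of four
forests (two random forests, two completely-random tree forests, 30
trees each) whose per-class probability vectors are concatenated with
the reduced features and passed to the next layer, the depth adapting to
out-of-fold validation accuracy.

The package also provides the surrounding experimental machinery: OTU
table parsing and rank aggregation (family/genus), metadata fusion
(age/gender/BMI covariates), repeated stratified k-fold evaluation with
micro/macro F1 and pooled confusion matrices, comparator front-ends
(PCA, SVD, LDA, LASSO selection) under a shared transform contract, and
a deterministic generator of microbiome-like benchmark data with
planted linear or concentric (non-linearly-separable) class structure.

## Worked example

```python
import numpy as np
from kpccf import (
    SyntheticSpec, generate_labeled, fit_kpccf, predict_kpccf, KpccfConfig,
)

ds = generate_labeled(SyntheticSpec(
    n_samples=200, n_features=40, sparsity=0.5,
    structure="concentric", seed=7,
))
train, test = np.arange(150), np.arange(150, 200)

from kpccf.taxa_io import LabeledDataset, SampleFeatureMatrix
train_ds = LabeledDataset(
    SampleFeatureMatrix(
        [ds.matrix.sample_ids[i] for i in train],
        ds.matrix.feature_names, ds.X[train],
    ),
    [ds.labels[i] for i in train],
)

model = fit_kpccf(train_ds, KpccfConfig())
labels, proba = predict_kpccf(model, ds.X[test])
acc = float(np.mean(labels == np.array(ds.labels)[test]))
print(f"components: {model.kpca.n_components}")
print(f"cascade layers: {model.cascade.n_layers} "
      f"({model.cascade.termination['stop_reason']})")
print(f"held-out accuracy: {acc:.3f}")
```

prints

```
components: 12
cascade layers: 2 (plateau)
held-out accuracy: 0.800
```

The generator planted three classes on concentric latent shells —
structure a hyperplane cannot see (a logistic model scores 0.50 on the
same split against a 0.54 majority rate) — and the kernel front-end
compressed 40 sparse count features into 12 components from which the
cascade separates the shells.

The same steps are available from the shell:

```sh
kpccf simulate --out-otu otu.tsv --out-meta meta.tsv --n-samples 120
kpccf prep --otu otu.tsv --meta meta.tsv --rank family --out table.tsv
kpccf train --data table.tsv --model-out model.joblib --seed 0
kpccf predict --model model.joblib --data table.tsv --out preds.tsv
kpccf evaluate --data table.tsv --out metrics.json --cv 4 --repeats 20
kpccf compare --data table.tsv --methods kpca,pca,svd,lda,lasso --out report.json
```

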