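import numpy as np
import pytest

from kpccf.synthetic_data import (
    SyntheticSpec,
    generate_labeled,
    generate_metadata,
    generate_otu_fixture,
)


@pytest.fixture(scope="session")
def otu_table():
    """Small OTU table: 5 families x 4 OTUs each, 30 samples, no truncation."""
    spec = SyntheticSpec(n_samples=30, sparsity=0.4, seed=7)
    return generate_otu_fixture(spec, n_families=5, otus_per_family=4)


@pytest.fixture(scope="session")
def labeled_small():
    """Small labeled concentric dataset for estimator smoke tests."""
    return generate_labeled(
        SyntheticSpec(n_samples=90, n_features=20, sparsity=0.4, seed=3)
    )


@pytest.fixture()
def metadata_for(labeled_small):
    return generate_metadata(
        labeled_small.matrix.sample_ids, labeled_small.labels, seed=5
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
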