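import numpy as np
import pandas as pd
import pytest

from binet.model import BooleanPathModel
from binet.synthetic import GeneratorBlueprint, generate_polarized_matrix


@pytest.fixture(scope="session")
def dataset():
    """Default planted-structure cohort at the standard noise level."""
    return generate_polarized_matrix(GeneratorBlueprint(seed=11, noise_sd=0.25))


@pytest.fixture(scope="session")
def fitted(dataset):
    """Fitted path model on the default cohort (shared; treat as read-only)."""
    return BooleanPathModel(dataset.matrix, dataset.annotation).fit()


@pytest.fixture(scope="session")
def dataset_clean():
    """Noise-free cohort (only the latent per-sample jitter remains)."""
    return generate_polarized_matrix(GeneratorBlueprint(seed=7, noise_sd=0.0))


def planted_cluster_map(dataset, clusters):
    """Map recovered cluster ids -> planted block ids by majority membership."""
    gene_to_block = {g: cid for cid, genes in dataset.gene_clusters.items()
                     for g in genes}
    mapping = {}
    for c in clusters:
        blocks = pd.Series([gene_to_block.get(g) for g in c.members])
        mapping[c.id] = blocks.mode().iloc[0]
    return mapping


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
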