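import warnings

import numpy as np
import pytest

from zfbrain.preprocess import normalize_log, pca
from zfbrain.syndata import SynthConfig, generate_counts

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def null_dataset():
    """Three balanced genotypes, no injected effect."""
    cfg = SynthConfig(n_genes=600, n_cells_per_genotype=300, n_clusters=4,
                      marker_log2fc=2.0, seed=42)
    return generate_counts(cfg)


@pytest.fixture(scope="session")
def separable_dataset():
    """Three well-separated clusters (strong markers)."""
    cfg = SynthConfig(n_genes=600, n_cells_per_genotype=300, n_clusters=3,
                      marker_log2fc=3.0, n_markers_per_cluster=20, seed=7)
    return generate_counts(cfg)


@pytest.fixture(scope="session")
def separable_embedding(separable_dataset):
    d = separable_dataset
    return pca(normalize_log(d), d.gene_ids, n_pcs=10)
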