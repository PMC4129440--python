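"""Shared fixtures: small generated genomes and studies with known truth."""

import numpy as np
import pandas as pd
import pytest

from aneuprot import synthetic_data as sd
from aneuprot.io_tables import QuantMatrix


@pytest.fixture(scope="session")
def genome():
    """Full-size yeast-like genome (4,800 genes, 16 chromosomes, 33% in complexes)."""
    return sd.generate_genome(seed=11)


@pytest.fixture(scope="session")
def small_genome():
    """Small genome for fast unit tests."""
    return sd.generate_genome(n_genes=600, n_chromosomes=8, complex_fraction=0.3, seed=5)


@pytest.fixture(scope="session")
def study(genome):
    """Default rich-medium 12-disome study with APS, ESR, and attenuation."""
    return sd.generate_study(genome=genome, seed=11)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 strains, hand-enterable values."""
    data = pd.DataFrame(
        {"disome01": [1.0, 0.2, -0.3], "disome02": [0.1, 1.1, np.nan]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return QuantMatrix(data, layer="protein")
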