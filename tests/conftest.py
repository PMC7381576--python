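import numpy as np
import pytest

from sievekit import GenotypeMatrix, SieveConfig, simulate_dataset


def make_gm(rows, locus_prefix="L", indiv_prefix="i"):
    """GenotypeMatrix from a nested list / array of genotype codes."""
    g = np.asarray(rows, dtype=np.int8)
    return GenotypeMatrix(
        g,
        np.array([f"{locus_prefix}{j}" for j in range(g.shape[1])], dtype=object),
        np.array([f"{indiv_prefix}{k}" for k in range(g.shape[0])], dtype=object),
    )


@pytest.fixture
def small_cfg():
    """Desk-scale two-year survey config used across module tests."""
    return SieveConfig(
        n_loci=400,
        n_larvae_per_pop_year=300,
        survey_sample_sizes={2014: 120, 2015: 40},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SieveConfig(
        n_loci=400,
        n_larvae_per_pop_year=300,
        survey_sample_sizes={2014: 120, 2015: 40},
        seed=42,
    )
    return simulate_dataset(cfg)
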