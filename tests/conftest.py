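import numpy as np
import pandas as pd
import pytest

from ketonet.io_formats import CountMatrix, GeneAnnotation, SampleInfo
from ketonet.synthetic_data import SyntheticConfig, TraitDriver, simulate_expression


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        seed=11,
        n_genes=300,
        module_sizes=[50, 40, 30],
        n_snps=3000,
        trait_drivers={"M1": TraitDriver("state", "K_Post", 2.5)},
        enriched_modules={"M1": 4.0},
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(counts, sample_info, annotation, truth) for a small planted dataset."""
    return simulate_expression(small_cfg)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[10, 20], [0, 5], [7, 7]]),
    )


@pytest.fixture
def tiny_annot() -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [100, 5000, 30000],
                "end": [1100, 7000, 40000],
                "length_bp": [1000, 2000, 10000],
            }
        )
    )


@pytest.fixture
def tiny_sample_info() -> SampleInfo:
    return SampleInfo(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "state": ["H_Pre", "K_Post"],
                "BHBA": [0.5, 2.1],
            }
        )
    )
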