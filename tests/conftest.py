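import pytest

from hprna.datamodel import PathwayUniverse
from hprna.synthetic import SyntheticConfig, generate_synthetic_dataset

#: Desk-scale generator configuration used across the suite: 4 pathway
#: clusters of 3, 20 drugs, 10 planted pairs, 1:5 negatives.
SMALL_CONFIG = dict(
    n_genes=800,
    n_pathways=12,
    genes_per_pathway=20,
    n_clusters=4,
    n_drugs=20,
    targets_per_drug=2,
    n_planted_positive_pairs=10,
    negative_ratio=5,
    n_ineffective_pairs=2,
)


@pytest.fixture(scope="session")
def toy_universe():
    """Three pathways over a 4-gene universe; p-values enumerable by hand."""
    return PathwayUniverse(
        [
            ("P1", ["g1", "g2", "g3"]),
            ("P2", ["g2", "g3", "g4"]),
            ("P3", ["g4"]),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    config = SyntheticConfig(**SMALL_CONFIG)
    return generate_synthetic_dataset(config, seed=7)


@pytest.fixture(scope="session")
def small_dataset_adjacent():
    config = SyntheticConfig(mechanism="adjacent_pathway", **SMALL_CONFIG)
    return generate_synthetic_dataset(config, seed=7)
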