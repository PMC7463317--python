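import numpy as np
import pytest

from popstruct.genotypes import GenotypeMatrix, SnpLocus
from popstruct.simulate import SimulationConfig, generate_dataset


def make_matrix(calls, codes=None, ids=None, locus_ids=None):
    """Build a small GenotypeMatrix from a nested list of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    codes = codes or ["P1"] * n
    ids = ids or [f"{codes[i]}_{i:03d}" for i in range(n)]
    locus_ids = locus_ids or [f"L{j}" for j in range(L)]
    loci = [SnpLocus(locus_id=x, alleles=("A", "G")) for x in locus_ids]
    return GenotypeMatrix(individuals=ids, collection_codes=codes, loci=loci, calls=calls)


@pytest.fixture
def two_pop_matrix():
    """Two collections of three individuals at two loci."""
    return make_matrix(
        [[0, 1], [1, 2], [0, 0], [2, 2], [1, 1], [2, 0]],
        codes=["A", "A", "A", "B", "B", "B"],
    )


@pytest.fixture
def three_cluster_data():
    """Three well-separated clusters of 50 individuals, 91 loci."""
    cfg = SimulationConfig(
        n_clusters=3,
        cluster_fst=(0.1, 0.1, 0.1),
        within_cluster_fst=0.0,
        n_collections_per_cluster=(1, 1, 1),
        n_individuals_per_collection=50,
        n_loci=91,
        seed=42,
    )
    return generate_dataset(cfg)
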