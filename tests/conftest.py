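import numpy as np
import pandas as pd
import pytest

from aoapan.io_formats import SequenceRecord
from aoapan.synthetic import PangenomeSpec, random_sequence, simulate_pangenome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def worked_matrix():
    """The hand-checkable 5-OG x 3-genome occupancy matrix.

    Rows A:111, B:111, C:110, D:100, E:001; exhaustive m=2 sampling gives
    pans (4, 5, 4) and cores (3, 2, 2) over the three genome pairs.
    """
    return pd.DataFrame(
        {
            "g1": [1, 1, 1, 1, 0],
            "g2": [1, 1, 1, 0, 0],
            "g3": [1, 1, 0, 0, 1],
        },
        index=list("ABCDE"),
        dtype="int8",
    )


@pytest.fixture(scope="session")
def planted_collection():
    """A small synthetic genome collection with planted family structure."""
    spec = PangenomeSpec(
        n_genomes=5,
        core_size=3,
        accessory_pool=[("acc0001", 0.6), ("acc0002", 0.4)],
        unique_rate=1.0,
        family_divergence=0.2,
        seed=11,
    )
    return simulate_pangenome(spec)


@pytest.fixture
def random_genome(rng):
    return SequenceRecord(id="gA", sequence=random_sequence(50000, rng))
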