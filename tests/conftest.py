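import numpy as np
import pytest

import phylocascade as pc

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return pc.parse_tree(TOY_NEWICK)


@pytest.fixture
def toy_dist(toy_tree):
    return pc.cophenetic_distances(toy_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_table(rng, n_samples=3, n_taxa=6, max_count=20, prefix=""):
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa)).astype(float)
    # ensure no empty samples
    counts[counts.sum(axis=1) == 0, 0] = 1
    return pc.OtuTable(
        [f"{prefix}s{i}" for i in range(n_samples)],
        [f"{prefix}t{j}" for j in range(n_taxa)],
        counts,
    )


@pytest.fixture(scope="session")
def cascade_small():
    """A small synthetic cascade study reused by integration tests."""
    return pc.generate_cascade_study(seed=5, n_taxa=60, community_size=800)
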