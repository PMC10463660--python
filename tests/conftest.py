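import numpy as np
import pytest

from phyloturn.io import CommunityTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    """3 samples x 4 ASVs with hand-checkable counts."""
    counts = np.array(
        [
            [5, 0, 3, 2],
            [0, 7, 1, 0],
            [4, 4, 0, 4],
        ]
    )
    return CommunityTable(["s1", "s2", "s3"], ["a1", "a2", "a3", "a4"], counts)


def random_table(rng, n_samples, n_asvs, depth=200, sparsity=0.3):
    """Random sparse count table with every sample non-empty."""
    comp = rng.dirichlet(np.ones(n_asvs), size=n_samples)
    comp[rng.random((n_samples, n_asvs)) < sparsity] = 0.0
    comp[np.arange(n_samples), rng.integers(n_asvs, size=n_samples)] += 0.5
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, c) for c in comp])
    ids = [f"s{i}" for i in range(n_samples)]
    asvs = [f"t{j}" for j in range(n_asvs)]
    return CommunityTable(ids, asvs, counts)
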