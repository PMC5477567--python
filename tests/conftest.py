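import numpy as np
import pytest

from fdmf import ScoreDataset, SyntheticSpec, generate


def random_mass(rng: np.random.Generator):
    """A random valid BPA drawn uniformly from the probability simplex."""
    v = rng.dirichlet(np.ones(3))
    return v


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset() -> ScoreDataset:
    """A small, clearly separable two-attribute dataset with two blocks."""
    rng = np.random.default_rng(7)
    n = 200
    labels = (rng.random(n) < 0.3).astype(int)
    base = np.where(labels == 1, 0.75, 0.25)
    scores = np.clip(
        base[:, None] + rng.normal(scale=0.08, size=(n, 2)), 0.001, 0.999
    )
    block = (np.arange(n) >= n // 2).astype(int)
    return ScoreDataset(scores, labels, block, ["a1", "a2"])


@pytest.fixture
def synthetic_dataset() -> ScoreDataset:
    """A moderate-size draw at the default study conditions (reduced blocks)."""
    return generate(SyntheticSpec(n_blocks=6, block_size=500, seed=11))
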