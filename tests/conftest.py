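import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rnathread.fixtures import FixtureConfig, generate_structure
from rnathread.scoring import load_scoring_tables


@pytest.fixture(scope="session")
def tables():
    return load_scoring_tables()


def random_structure(seed: int, pk: float = 0.3, length=(40, 60)):
    cfg = FixtureConfig(seed=seed, pseudoknot_probability=pk, length_range=length)
    return generate_structure(cfg, 0)


def random_pairs(rng: np.random.Generator, n: int, n_pairs: int) -> frozenset:
    """Uniform random valid pair set (no position reuse) over 1..n."""
    positions = list(rng.permutation(np.arange(1, n + 1)))
    pairs = set()
    while len(pairs) < n_pairs and len(positions) >= 2:
        i, j = positions.pop(), positions.pop()
        i, j = int(min(i, j)), int(max(i, j))
        pairs.add((i, j))
    return frozenset(pairs)
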