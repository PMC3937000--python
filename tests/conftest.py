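import numpy as np
import pytest

from genoprof.lineage_sim import random_genome
from genoprof.spiddos import GenomeProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20140219)


@pytest.fixture
def genome_1kb():
    return random_genome(1000, seed=7)


def make_profile(label: str, n: int, seed: int) -> GenomeProfile:
    """Random profile in the normalized frame: mobility in [0, 1],
    temperature near the reference range."""
    r = np.random.default_rng(seed)
    pts = np.column_stack([r.uniform(0.0, 1.0, n), r.uniform(55.0, 65.0, n)])
    return GenomeProfile(label, pts)


@pytest.fixture
def profile_factory():
    return make_profile
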