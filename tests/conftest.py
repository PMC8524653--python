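import numpy as np
import pytest

import seqforge as sf


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def usage_table():
    return sf.CodonUsageTable.random(np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_construct():
    """A 2-TU benchmark construct (~3.5 kb), enough for every operator."""
    return sf.generate_construct(sf.BenchmarkSpec(num_tus=2, seed=11))


@pytest.fixture(scope="session")
def medium_construct():
    """A 5-TU benchmark construct at the standard study scale."""
    return sf.generate_construct(sf.BenchmarkSpec(num_tus=5, seed=23))


@pytest.fixture()
def default_cfg():
    return sf.OptimizerConfig()


def make_solution(construct, cfg=None, seed=0):
    """One evaluatable solution over a construct with a random partition."""
    from seqforge.optimizer import random_partition

    cfg = cfg or sf.OptimizerConfig()
    blocks = random_partition(len(construct.seq), cfg, np.random.default_rng(seed))
    return sf.Solution(construct.seq, blocks, construct.cds_features)
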