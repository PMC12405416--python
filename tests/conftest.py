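import random

import pytest

from rtcnspace import poset, system, worked_examples
from rtcnspace.simulate import SimConfig, default_taxa, random_maximal_chain


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


@pytest.fixture(scope="session")
def taxa3():
    return default_taxa(3)


@pytest.fixture(scope="session")
def taxa4():
    return default_taxa(4)


@pytest.fixture(scope="session")
def chains_n3(taxa3):
    return list(poset.enumerate_maximal_chains(taxa3))


@pytest.fixture(scope="session")
def chains_n4(taxa4):
    return list(poset.enumerate_maximal_chains(taxa4))


@pytest.fixture(scope="session")
def members_n4(chains_n4):
    """Every poset member on four taxa, collected from all maximal chains."""
    return sorted({s for chain in chains_n4 for s in chain},
                  key=lambda s: (len(s), sorted(sorted(c) for c in s)))


def random_chains(n, count, p_ret=0.4, seed=20260927):
    rng = random.Random(seed + n)
    cfg = SimConfig(n=n, p_ret=p_ret, seed=0)
    return [random_maximal_chain(cfg, rng) for _ in range(count)]
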