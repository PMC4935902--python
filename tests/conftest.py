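import pytest

from phylonetdist import (
    GeneratorConfig,
    load_fixture,
    random_network,
)


@pytest.fixture(scope="session")
def fig1_pair():
    return load_fixture("fig1_N1"), load_fixture("fig1_N2")


@pytest.fixture(scope="session")
def fig4_pair():
    return load_fixture("fig4_N1"), load_fixture("fig4_N2")


@pytest.fixture(scope="session")
def small_random_pool():
    """Seeded pool of small strict networks on a shared 4-taxon set."""
    pool = []
    for seed in range(40):
        cfg = GeneratorConfig(n_leaves=4, n_reticulations=seed % 3, seed=seed)
        pool.append(random_network(cfg))
    return pool


@pytest.fixture(scope="session")
def partly_reduced_pool():
    """Seeded pool of partly reduced networks (<= 12 nodes) on 4 taxa."""
    pool = []
    for seed in range(60):
        cfg = GeneratorConfig(
            n_leaves=4, n_reticulations=seed % 3, seed=1000 + seed, mode="partly_reduced"
        )
        net = random_network(cfg)
        if len(net) <= 12:
            pool.append(net)
    return pool
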