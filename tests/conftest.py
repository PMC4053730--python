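import io

import pytest

from votax.classify import ClassifierConfig
from votax.simulate import make_toy_taxonomy
from votax.taxonomy import load_taxdump


def store_from_toy(toy):
    return load_taxdump(io.StringIO(toy.nodes_dmp), io.StringIO(toy.names_dmp))


@pytest.fixture(scope="session")
def toy():
    """29-node taxonomy: 3 organisms plus every pathology decoy."""
    return make_toy_taxonomy(3, rank_gap=True, generic_leaves=3, kingdom_only_leaves=2)


@pytest.fixture(scope="session")
def store(toy):
    return store_from_toy(toy)


@pytest.fixture(scope="session")
def oracle_toy():
    """Exactly 20 nodes: 2 organisms, rank gap, one generic, one partial."""
    t = make_toy_taxonomy(2, rank_gap=True, generic_leaves=1, kingdom_only_leaves=1)
    assert len(t.lineages) == 20
    return t


@pytest.fixture(scope="session")
def oracle_store(oracle_toy):
    return store_from_toy(oracle_toy)


@pytest.fixture(scope="session")
def its_cfg():
    return ClassifierConfig.from_preset("its")


@pytest.fixture(scope="session")
def cfg_18s():
    return ClassifierConfig.from_preset("18s")
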