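import warnings

import pytest

import pleiopipe as pp
from pleiopipe import grn as grn_mod
from pleiopipe import synthetic as syn


@pytest.fixture(scope="session")
def world():
    """Default desk-scale world: 2 x 1 Mb chromosomes, 20 planted pairs."""
    return pp.gen_world(pp.SimConfig(), seed=1)


@pytest.fixture(scope="session")
def big_world():
    """World sized so ~2,000 spatial candidates carry the 20 planted pairs."""
    cfg = pp.SimConfig(n_snps=2000, n_true_genes=5)
    return pp.gen_world(cfg, seed=7)


@pytest.fixture(scope="session")
def eqtl_table(world):
    return pp.gen_eqtl_table(world, seed=2)


@pytest.fixture(scope="session")
def built_grn(world, eqtl_table):
    snp_frag = grn_mod.assign_fragments(world.snps, world.fragments)
    pairs = grn_mod.find_spatial_pairs(snp_frag, world.genes, world.fragments, world.contacts)
    return grn_mod.call_eqtls(pairs, eqtl_table, world.snps, world.genes)


@pytest.fixture(scope="session")
def catalog(world):
    return pp.gen_gwas_catalog(world, n_traits=50, pleiotropy_frac=0.8, seed=3)


@pytest.fixture(scope="session")
def ppin_graph(world):
    return pp.gen_ppin(world, seed=4)


@pytest.fixture(scope="session")
def ld_resource(world):
    return world.ld_resource()


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="level .*: no eQTLs")
        yield
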