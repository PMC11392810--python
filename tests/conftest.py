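import numpy as np
import pytest

from shmseq import core_io, fixtures


@pytest.fixture(scope="session")
def layout() -> core_io.ArrayLayout:
    return core_io.default_layout()


@pytest.fixture(scope="session")
def small_config() -> fixtures.FixtureConfig:
    """3 genera x 2 species, strongly diverged: easy classification fixture."""
    return fixtures.FixtureConfig(
        seed=7,
        n_genera=3,
        species_per_genus=2,
        n_species=None,
        ref_length=1200,
        probe_site_position=800,
        variable_region_span=250,
        branch_substitution_rate=0.05,
    )


@pytest.fixture(scope="session")
def small_tree(small_config):
    return fixtures.make_taxonomy(small_config)


@pytest.fixture(scope="session")
def small_refs(small_config, small_tree):
    return fixtures.make_references(small_tree, small_config)


@pytest.fixture(scope="session")
def toy_tree():
    """Hand-built taxonomy: 1 family, 2 genera, 3 species."""
    n = core_io.TaxonNode
    return core_io.TaxonomyTree([
        n("root", "root", "root", None),
        n("f0", "F0", "family", "root"),
        n("gA", "GenusA", "genus", "f0"),
        n("gB", "GenusB", "genus", "f0"),
        n("sA1", "A1", "species", "gA"),
        n("sA2", "A2", "species", "gA"),
        n("sB1", "B1", "species", "gB"),
    ])


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
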