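import numpy as np
import pytest

from splinterkit.chem import VdwRadiusTable
from splinterkit.energy import SurrogateBackend
from splinterkit.fixtures import make_fixtures
from splinterkit.pairing import enumerate_site_dimers


@pytest.fixture(scope="session")
def fixture_set():
    return make_fixtures()


@pytest.fixture(scope="session")
def radii():
    return VdwRadiusTable.default()


@pytest.fixture(scope="session")
def site_dimers(fixture_set):
    return enumerate_site_dimers(
        fixture_set.protein_sites(), fixture_set.ligand_sites()
    )


@pytest.fixture(scope="session")
def surrogate(fixture_set):
    return SurrogateBackend(fixture_set.surrogate_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def find_monomer(fixture_set, name):
    for m in fixture_set.protein_monomers + fixture_set.ligand_monomers:
        if m.name == name:
            return m
    raise KeyError(name)


def sites_of(fixture_set, name, category=None):
    out = fixture_set.sites[name]
    if category is not None:
        out = [s for s in out if s.category == category]
    return out
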