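import numpy as np
import pytest

from helifil.lattice import LatticeSpec, build_mt_lattice
from helifil.synth import ToyTemplateSpec, toy_templates
from helifil.transition import mt_to_hf_pipeline

#: mean EM filament geometry used across tests (Angstrom)
EM_MEAN = {"diameter": 404.0, "coil_separation": 193.0}


@pytest.fixture(scope="session")
def canonical_spec():
    """Canonical 13-3 lattice, 195 heterodimers."""
    return LatticeSpec()


@pytest.fixture(scope="session")
def small_spec():
    """Two-turn 13-3 lattice for cheap structural tests."""
    return LatticeSpec(n_dimers=26)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyTemplateSpec(seed=11)


@pytest.fixture(scope="session")
def templates(toy_spec):
    return toy_templates(toy_spec)


@pytest.fixture(scope="session")
def hf_full(canonical_spec):
    """Full 195-dimer transition at the mean EM geometry (run once)."""
    return mt_to_hf_pipeline(canonical_spec, EM_MEAN, seed=7)


@pytest.fixture()
def small_lattice(small_spec):
    return build_mt_lattice(small_spec)
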