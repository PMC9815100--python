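import numpy as np
import pytest

from mdmx import (
    ToyCrystalSpec,
    UnitCell,
    make_ensemble,
    make_toy_crystal,
    spacegroup_from_symbol,
)


@pytest.fixture(scope="session")
def p1_cell():
    return UnitCell(12.0, 13.0, 14.0)


@pytest.fixture(scope="session")
def triclinic_cell():
    return UnitCell(11.0, 13.0, 15.0, 83.0, 97.0, 104.0)


@pytest.fixture(scope="session")
def p212121():
    return spacegroup_from_symbol("P 21 21 21")


@pytest.fixture(scope="session")
def toy_p1():
    """Small P1 crystal: 2 residues + 1 water, with ground-truth manifest."""
    spec = ToyCrystalSpec(
        spacegroup="P 1",
        cell_lengths=(12.0, 13.0, 14.0),
        n_residues=2,
        water_sites_frac=((0.7, 0.2, 0.3),),
        seed=11,
    )
    return make_toy_crystal(spec)


@pytest.fixture(scope="session")
def toy_p212121():
    """P2₁2₁2₁ crystal with waters and ions, with ground-truth manifest."""
    spec = ToyCrystalSpec(
        spacegroup="P 21 21 21",
        cell_lengths=(20.0, 24.0, 28.0),
        n_residues=4,
        water_sites_frac=((0.6, 0.15, 0.2), (0.75, 0.4, 0.35)),
        ions=("MG", "CL"),
        seed=11,
    )
    return make_toy_crystal(spec)


@pytest.fixture(scope="session")
def toy_ensemble(toy_p212121):
    asu, _ = toy_p212121
    return make_ensemble(asu, 8, sigma=0.15, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
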