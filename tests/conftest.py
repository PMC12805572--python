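import numpy as np
import pytest

from sitefield.dsf import DSFParams
from sitefield.ewald import EwaldParams
from sitefield.fixtures import make_toy_molecular_crystal


@pytest.fixture(scope="session")
def toy24():
    """24-molecule toy crystal with bonds (96 atoms), fixed seed."""
    return make_toy_molecular_crystal(n_molecules=24, seed=5)


@pytest.fixture(scope="session")
def toy32():
    """32-molecule (2×2×2 cell) toy crystal with bonds."""
    return make_toy_molecular_crystal(2, seed=1)


@pytest.fixture(scope="session")
def dsf_params():
    return DSFParams()


@pytest.fixture(scope="session")
def ewald_params():
    return EwaldParams()


def finite_difference_force_error(energy_fn, config, atoms, h=1e-4):
    """Max |analytic − central-difference| force component over given atoms."""
    res = energy_fn(config)
    errs = []
    for a in atoms:
        for ax in range(3):
            plus = config.positions.copy()
            plus[a, ax] += h
            minus = config.positions.copy()
            minus[a, ax] -= h
            e_plus = energy_fn(config.replace_positions(plus)).energy
            e_minus = energy_fn(config.replace_positions(minus)).energy
            errs.append(abs(-(e_plus - e_minus) / (2 * h) - res.forces[a, ax]))
    return max(errs)
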