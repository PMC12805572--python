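"""Deterministic synthetic-system generators.

Every generator is a pure function of its parameters and an integer seed, so
all validation runs offline and bit-reproducibly.  The toy molecular crystal
stands in for a molecular semiconductor supercell: an fcc lattice of planar
4-atom molecules whose neutral charges sum to zero (dipolar pattern) and
whose charged-state charges sum to +1 e, which exercises both correction
classes of the addition-subtraction scheme.  Rock-salt and single-charge
(Wigner) lattices provide literature constants for validating the Ewald
oracle itself.
"""

from __future__ import annotations

import numpy as np

from .core import (InvalidParameterError, MoleculeChargeSpec, PeriodicCell,
                   SystemConfiguration)
from .md import BondTerm, LennardJonesTable
from .reorg import GapSeries
from .transport import SiteHamiltonianTrajectory
from .units import K_B

# fcc basis (fractional) — 4 molecules per conventional cubic cell
_FCC_BASIS = np.array([[0.0, 0.0, 0.0], [0.0, 0.5, 0.5],
                       [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])

#: Toy molecule: one heavy center bonded to three planar peripheral atoms.
TOY_BOND_LENGTH = 1.10        # Å, neutral equilibrium
TOY_BOND_DELTA = 0.05         # Å, charged-state bond elongation before β scaling
TOY_BOND_K = 20.0             # eV/Å²
TOY_BETA = 0.88
TOY_NEUTRAL_CHARGES = np.array([-0.30, 0.14, 0.10, 0.06])
TOY_DELTA_CHARGES = np.array([0.40, 0.20, 0.20, 0.20])   # sums to +1 e


def make_nacl(n_cells_per_axis: int, nearest_neighbor_distance: float = 2.82
              ) -> SystemConfiguration:
    """Rock-salt lattice, ±1 e ions, one 'molecule' per Na–Cl ion pair."""
    if n_cells_per_axis < 1:
        raise InvalidParameterError("need at least one unit cell")
    a = 2.0 * nearest_neighbor_distance
    n = n_cells_per_axis
    cell = PeriodicCell(np.eye(3) * a * n)
    na_frac = _FCC_BASIS
    cl_frac = _FCC_BASIS + np.array([0.5, 0.0, 0.0])
    positions, elements, mol_idx = [], [], []
    mol = 0
    for ix in range(n):
        for iy in range(n):
            for iz in range(n):
                off = np.array([ix, iy, iz], float)
                for b in range(4):
                    positions.append((na_frac[b] + off) / n)
                    positions.append((cl_frac[b] + off) / n)
                    elements += ["Na", "Cl"]
                    mol_idx += [mol, mol]
                    mol += 1
    pos = cell.cartesian(np.array(positions))
    spec = MoleculeChargeSpec(neutral_charges=np.array([1.0, -1.0]),
                              charged_charges=np.array([2.0, -1.0]),
                              net_charge=1.0)
    return SystemConfiguration(cell, pos, elements, np.array(mol_idx), spec)


def make_wigner(box_length: float = 10.0) -> SystemConfiguration:
    """A single +1 e point charge in a cubic cell with neutralizing background."""
    cell = PeriodicCell(np.eye(3) * box_length)
    spec = MoleculeChargeSpec(neutral_charges=np.array([0.0]),
                              charged_charges=np.array([1.0]),
                              net_charge=1.0)
    return SystemConfiguration(cell, np.zeros((1, 3)), ["X"], np.array([0]),
                               spec, active_state=0)


def _toy_molecule_geometry() -> np.ndarray:
    """4-atom planar Y: heavy center plus three peripherals in the xy-plane."""
    angles = np.deg2rad([90.0, 210.0, 330.0])
    ring = TOY_BOND_LENGTH * np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(3)], axis=1)
    return np.vstack([np.zeros(3), ring])


def _cells_tuple(n_cells) -> tuple[int, int, int]:
    if np.isscalar(n_cells):
        return (int(n_cells),) * 3
    t = tuple(int(c) for c in n_cells)
    if len(t) != 3:
        raise InvalidParameterError("n_cells must be a scalar or a 3-tuple")
    return t


def _cells_for_molecule_count(n_molecules: int) -> tuple[int, int, int]:
    """Smallest (a ≤ b ≤ c) cell grid with 4·a·b·c = n_molecules."""
    if n_molecules % 4:
        raise InvalidParameterError("toy crystal molecule count must be 4·a·b·c")
    target = n_molecules // 4
    best = None
    for a in range(1, target + 1):
        if target % a:
            continue
        for b in range(a, target // a + 1):
            if (target // a) % b:
                continue
            c = target // (a * b)
            if c < b:
                continue
            shape = (a, b, c)
            score = c - a  # prefer near-cubic grids
            if best is None or score < best[0]:
                best = (score, shape)
    assert best is not None
    return best[1]


def make_toy_molecular_crystal(n_cells=None, *, n_molecules: int | None = None,
                               lattice_constant: float = 7.0, seed: int = 0,
                               orientation_disorder: bool = True
                               ) -> tuple[SystemConfiguration, list[BondTerm]]:
    """fcc molecular crystal of planar 4-atom molecules, with harmonic bonds.

    Neutral charges per molecule sum to 0 (dipolar pattern) and charged-state
    charges to +1 e.  Each molecule gets a seeded random orientation so the
    lattice has no accidental symmetry.  Returns the configuration and the
    bond list (three bonds per molecule, distinct neutral/charged equilibrium
    lengths r⁰c = r⁰n + β·Δr with β = 0.88).
    """
    if n_cells is None:
        if n_molecules is None:
            raise InvalidParameterError("give n_cells or n_molecules")
        cells = _cells_for_molecule_count(n_molecules)
    else:
        cells = _cells_tuple(n_cells)
    rng = np.random.default_rng(seed)
    a0 = lattice_constant
    lattice = np.diag([a0 * c for c in cells])
    cell = PeriodicCell(lattice)
    template = _toy_molecule_geometry()

    positions, elements, mol_idx = [], [], []
    mol = 0
    for ix in range(cells[0]):
        for iy in range(cells[1]):
            for iz in range(cells[2]):
                for b in range(4):
                    frac = (_FCC_BASIS[b] + [ix, iy, iz]) / np.array(cells)
                    center = cell.cartesian(frac)
                    if orientation_disorder:
                        rot = _random_rotation(rng)
                    else:
                        rot = np.eye(3)
                    positions.append(template @ rot.T + center)
                    elements += ["X", "C", "C", "C"]
                    mol_idx += [mol] * 4
                    mol += 1
    pos = np.vstack(positions)
    spec = MoleculeChargeSpec(
        neutral_charges=TOY_NEUTRAL_CHARGES,
        charged_charges=TOY_NEUTRAL_CHARGES + TOY_DELTA_CHARGES,
        net_charge=1.0,
    )
    config = SystemConfiguration(cell, pos, elements, np.array(mol_idx), spec)
    bonds = []
    r0c = TOY_BOND_LENGTH + TOY_BETA * TOY_BOND_DELTA
    for m in range(mol):
        base = 4 * m
        for p in (1, 2, 3):
            bonds.append(BondTerm(base, base + p, TOY_BOND_K,
                                  TOY_BOND_LENGTH, r0c))
    return config, bonds


def toy_lennard_jones() -> LennardJonesTable:
    """Weak repulsive-core LJ between heavy centers, stabilizing the lattice."""
    return LennardJonesTable(epsilon={("X", "X"): 0.01, ("X", "C"): 0.004,
                                      ("C", "C"): 0.002},
                             sigma={("X", "X"): 4.0, ("X", "C"): 3.2,
                                    ("C", "C"): 2.6},
                             r_cut=9.0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def displace_ensemble(config: SystemConfiguration, n_snapshots: int,
                      rms_amplitude: float, seed: int = 0
                      ) -> list[SystemConfiguration]:
    """Seeded thermal-like ensemble: isotropic Gaussian per-atom displacements.

    The per-atom RMS displacement of the ensemble matches ``rms_amplitude``
    in expectation (√3·σ_component).
    """
    rng = np.random.default_rng(seed)
    sigma = rms_amplitude / np.sqrt(3.0)
    out = []
    for _ in range(n_snapshots):
        disp = rng.normal(0.0, sigma, size=config.positions.shape)
        out.append(config.replace_positions(config.positions + disp))
    return out


def make_gap_series(lambda_target: float, temperature: float, n: int,
                    seed: int = 0, linear_response: bool = True,
                    variance: float | None = None,
                    sampling_interval_fs: float = 1000.0) -> GapSeries:
    """Gaussian vertical-energy-gap samples with mean λ.

    Under linear response the gap variance is tied to the mean by
    σ² = 2 k_B T λ, which makes the Stokes-shift and variance estimators
    agree; ``linear_response=False`` decouples them via ``variance``.
    """
    if lambda_target <= 0 or temperature <= 0:
        raise InvalidParameterError("lambda and T must be positive")
    if n < 2:
        raise InvalidParameterError("gap series needs at least 2 samples")
    rng = np.random.default_rng(seed)
    var = 2.0 * K_B * temperature * lambda_target if linear_response else variance
    if var is None or var < 0:
        raise InvalidParameterError("explicit non-negative variance required")
    gaps = rng.normal(lambda_target, np.sqrt(var), size=n)
    return GapSeries(gaps=gaps, temperature=temperature,
                     sampling_interval_fs=sampling_interval_fs)


def make_hamiltonian_chain(n_sites: int, coupling: float,
                           site_energy_sigma: float, correlation_time: float,
                           dt: float, n_frames: int, seed: int = 0,
                           site_spacing: float = 5.0) -> SiteHamiltonianTrajectory:
    """Nearest-neighbor chain with Ornstein–Uhlenbeck site-energy noise.

    Site energies follow independent stationary OU processes with standard
    deviation ``site_energy_sigma`` (eV) and correlation time
    ``correlation_time`` (fs); couplings are constant.  σ = 0 yields a static
    Hamiltonian.
    """
    if n_sites < 2 or dt <= 0 or n_frames < 1 or correlation_time <= 0:
        raise InvalidParameterError("invalid chain parameters")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * dt
    eps = np.zeros((n_frames, n_sites))
    if site_energy_sigma > 0:
        decay = np.exp(-dt / correlation_time)
        noise_scale = site_energy_sigma * np.sqrt(1.0 - decay**2)
        eps[0] = rng.normal(0.0, site_energy_sigma, n_sites)
        for t in range(1, n_frames):
            eps[t] = decay * eps[t - 1] + rng.normal(0.0, noise_scale, n_sites)
    h_off = np.zeros((n_sites, n_sites))
    for k in range(n_sites - 1):
        h_off[k, k + 1] = h_off[k + 1, k] = coupling
    couplings = np.broadcast_to(h_off, (n_frames, n_sites, n_sites)).copy()
    site_positions = np.zeros((n_sites, 3))
    site_positions[:, 0] = np.arange(n_sites) * site_spacing
    return SiteHamiltonianTrajectory(times=times, site_energies=eps,
                                     couplings=couplings,
                                     site_positions=site_positions)
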