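"""Domain types and periodic-cell geometry shared by all summation modules.

The central object is :class:`SystemConfiguration`: a periodic cell holding
``N_mol`` identical molecules of ``N_apm`` atoms each, where every molecule
carries two charge parameter sets — neutral charges ``q^n`` (summing to zero)
and charged-state charges ``q^c`` (summing to the net molecular charge ``q``).
Charge state ``I`` means molecule ``I`` uses ``q^c`` while every other
molecule uses ``q^n``; state ``-1`` is the all-neutral reference.

Pair interactions over periodic images are enumerated explicitly (not by the
minimum-image convention) so that real-space cutoffs larger than half the box
length are supported.  Each (home atom i, atom j in image n) interaction is
counted exactly once per unit cell, equivalent to the usual ½ΣΣΣ'
double-counted lattice sum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


class InvalidParameterError(ValueError):
    """Raised for non-physical run parameters (negative cutoffs etc.)."""


class StructuralError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass(frozen=True)
class PeriodicCell:
    """Parallelepiped cell; lattice vectors are the *rows* of a 3×3 matrix (Å)."""

    lattice_vectors: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.lattice_vectors, dtype=float).reshape(3, 3)
        object.__setattr__(self, "lattice_vectors", lv)
        if np.linalg.det(lv) <= 0:
            raise InvalidParameterError(
                "lattice vectors must form a right-handed cell with positive volume"
            )

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.lattice_vectors))

    @property
    def reciprocal_vectors(self) -> np.ndarray:
        """Rows b_i with a_i·b_j = 2π δ_ij."""
        return 2.0 * np.pi * np.linalg.inv(self.lattice_vectors).T

    def fractional(self, positions: np.ndarray) -> np.ndarray:
        return np.asarray(positions) @ np.linalg.inv(self.lattice_vectors)

    def cartesian(self, fractional: np.ndarray) -> np.ndarray:
        return np.asarray(fractional) @ self.lattice_vectors

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        frac = self.fractional(positions) % 1.0
        return self.cartesian(frac)

    def plane_spacings(self) -> np.ndarray:
        """Perpendicular distance between lattice planes along each axis."""
        recip = self.reciprocal_vectors
        return 2.0 * np.pi / np.linalg.norm(recip, axis=1)


@dataclass(frozen=True)
class MoleculeChargeSpec:
    """Neutral/charged point-charge sets for one molecular species (units of e)."""

    neutral_charges: np.ndarray
    charged_charges: np.ndarray
    net_charge: float

    def __post_init__(self) -> None:
        qn = np.asarray(self.neutral_charges, dtype=float)
        qc = np.asarray(self.charged_charges, dtype=float)
        object.__setattr__(self, "neutral_charges", qn)
        object.__setattr__(self, "charged_charges", qc)
        if qn.shape != qc.shape:
            raise StructuralError("neutral and charged charge sets differ in length")
        if abs(qn.sum()) > 1e-9:
            raise StructuralError(f"neutral charges must sum to 0, got {qn.sum():.3e}")
        if abs(qc.sum() - self.net_charge) > 1e-9:
            raise StructuralError(
                f"charged charges must sum to the net charge {self.net_charge}, "
                f"got {qc.sum():.3e}"
            )

    @property
    def n_atoms_per_molecule(self) -> int:
        return len(self.neutral_charges)


@dataclass
class SystemConfiguration:
    """Periodic configuration with per-molecule dual charge parameters.

    ``positions`` are Cartesian Å, shape (N_at, 3); molecules are stored
    whole (never wrapped across the boundary) so intramolecular distances are
    physical bond distances.  ``active_state`` selects the charged molecule;
    ``-1`` is the all-neutral reference state.
    """

    cell: PeriodicCell
    positions: np.ndarray
    elements: list[str]
    molecule_index: np.ndarray
    charge_spec: MoleculeChargeSpec
    active_state: int = -1

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.molecule_index = np.asarray(self.molecule_index, dtype=int)
        if self.positions.shape != (len(self.elements), 3):
            raise StructuralError("positions must be (N_at, 3) matching elements")
        if not np.all(np.isfinite(self.positions)):
            raise StructuralError("positions must be finite")
        if len(self.molecule_index) != len(self.elements):
            raise StructuralError("molecule_index length mismatch")
        n_apm = self.charge_spec.n_atoms_per_molecule
        counts = np.bincount(self.molecule_index, minlength=self.n_molecules)
        if not np.all(counts == n_apm):
            raise StructuralError(
                f"every molecule must have exactly {n_apm} atoms; counts={counts}"
            )
        if not (-1 <= self.active_state < self.n_molecules):
            raise InvalidParameterError(
                f"active_state {self.active_state} outside [-1, {self.n_molecules})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1 if len(self.molecule_index) else 0

    @property
    def n_atoms_per_molecule(self) -> int:
        return self.charge_spec.n_atoms_per_molecule

    def atom_index_in_molecule(self) -> np.ndarray:
        order = np.zeros(self.n_atoms, dtype=int)
        seen: dict[int, int] = {}
        for a, m in enumerate(self.molecule_index):
            order[a] = seen.get(int(m), 0)
            seen[int(m)] = order[a] + 1
        return order

    def charges(self, state: int | None = None) -> np.ndarray:
        """Per-atom charges for the given charge state (default: active_state)."""
        state = self.active_state if state is None else state
        if not (-1 <= state < self.n_molecules):
            raise InvalidParameterError(f"charge state {state} out of range")
        idx = self.atom_index_in_molecule()
        q = self.charge_spec.neutral_charges[idx].copy()
        if state >= 0:
            mask = self.molecule_index == state
            q[mask] = self.charge_spec.charged_charges[idx[mask]]
        return q

    def neutral_charges(self) -> np.ndarray:
        return self.charges(-1)

    def delta_charges(self) -> np.ndarray:
        """q^c − q^n per atom position (state-independent template)."""
        idx = self.atom_index_in_molecule()
        return (self.charge_spec.charged_charges - self.charge_spec.neutral_charges)[idx]

    def total_charge(self, state: int | None = None) -> float:
        state = self.active_state if state is None else state
        return 0.0 if state == -1 else self.charge_spec.net_charge

    def with_state(self, state: int) -> "SystemConfiguration":
        return SystemConfiguration(
            cell=self.cell,
            positions=self.positions,
            elements=self.elements,
            molecule_index=self.molecule_index,
            charge_spec=self.charge_spec,
            active_state=state,
        )

    def replace_positions(self, positions: np.ndarray) -> "SystemConfiguration":
        return SystemConfiguration(
            cell=self.cell,
            positions=np.asarray(positions, dtype=float),
            elements=self.elements,
            molecule_index=self.molecule_index,
            charge_spec=self.charge_spec,
            active_state=self.active_state,
        )


@dataclass
class EnergyForces:
    """Energy (eV) with per-atom forces (eV/Å) and a named component breakdown."""

    energy: float
    forces: np.ndarray
    components: dict[str, float] = field(default_factory=dict)


def enumerate_images(cell: PeriodicCell, r_cut: float,
                     frac_spread: np.ndarray | None = None) -> np.ndarray:
    """Lattice translation vectors n whose image cell can interact within r_cut.

    Returns a conservative superset of integer-combination translations
    (Cartesian, shape (M, 3)) including n = 0.  ``frac_spread`` widens the
    search when atom positions extend outside the home cell (whole molecules).
    Supports r_cut larger than half the shortest box length.
    """
    if r_cut <= 0:
        raise InvalidParameterError("r_cut must be positive")
    spacings = cell.plane_spacings()
    extra = np.zeros(3) if frac_spread is None else np.asarray(frac_spread, float)
    bounds = np.ceil(r_cut / spacings + extra).astype(int)
    ranges = [range(-b, b + 1) for b in bounds]
    ints = np.array(list(itertools.product(*ranges)), dtype=float)
    # put n = 0 first for a deterministic, readable ordering
    order = np.lexsort((ints[:, 2], ints[:, 1], ints[:, 0], (ints != 0).any(axis=1)))
    return ints[order] @ cell.lattice_vectors


@dataclass
class PairTable:
    """All interacting pairs within r_cut, each counted once per unit cell.

    ``i`` is always the home-cell atom; ``j`` the partner atom whose image is
    displaced by ``shift``.  Self-images (i == j, n ≠ 0) appear once per
    ±n pair of translations, consistent with the ½ΣΣΣ' convention.
    """

    i: np.ndarray
    j: np.ndarray
    shift: np.ndarray       # (P, 3) Cartesian lattice translations
    distance: np.ndarray    # (P,)
    r_cut: float

    @property
    def count(self) -> int:
        return len(self.i)

    def vectors(self, positions: np.ndarray) -> np.ndarray:
        """R_j + n − R_i for each pair, from *current* positions."""
        return positions[self.j] + self.shift - positions[self.i]

    def distances(self, positions: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.vectors(positions), axis=1)


def build_pair_table(config: SystemConfiguration, r_cut: float,
                     skin: float = 0.0) -> PairTable:
    """Enumerate unique pairs with |R_ij + n| ≤ r_cut (+skin), vectorized.

    Uniqueness convention: for n = 0 only i < j is kept; for n ≠ 0 every
    ordered (i, j) is a distinct interaction but each ±n image pair is
    generated once by keeping exactly one translation of every {n, −n} pair.
    """
    if r_cut <= 0:
        raise InvalidParameterError("r_cut must be positive")
    reach = r_cut + skin
    pos = config.positions
    frac = config.cell.fractional(pos)
    spread = frac.max(axis=0) - frac.min(axis=0)
    images = enumerate_images(config.cell, reach, frac_spread=spread)
    n_at = config.n_atoms

    ii, jj, ss, dd = [], [], [], []
    # classify translations into n = 0 and one representative of each ±n pair
    for shift in images:
        if np.allclose(shift, 0.0):
            continue
        key = tuple(np.round(config.cell.fractional(shift)).astype(int))
        if key < tuple(-k for k in key):
            continue  # keep only one of ±n
        disp = pos[None, :, :] + shift[None, None, :] - pos[:, None, :]
        dist = np.linalg.norm(disp, axis=-1)
        a, b = np.nonzero(dist <= reach)
        ii.append(a)
        jj.append(b)
        ss.append(np.broadcast_to(shift, (len(a), 3)))
        dd.append(dist[a, b])

    disp0 = pos[None, :, :] - pos[:, None, :]
    dist0 = np.linalg.norm(disp0, axis=-1)
    iu, ju = np.triu_indices(n_at, k=1)
    keep = dist0[iu, ju] <= reach
    ii.append(iu[keep])
    jj.append(ju[keep])
    ss.append(np.zeros((int(keep.sum()), 3)))
    dd.append(dist0[iu, ju][keep])

    i = np.concatenate(ii) if ii else np.empty(0, int)
    j = np.concatenate(jj) if jj else np.empty(0, int)
    shift_arr = np.vstack(ss) if ss else np.empty((0, 3))
    dist_arr = np.concatenate(dd) if dd else np.empty(0)
    # deterministic ordering
    order = np.lexsort((np.round(dist_arr, 10), j, i))
    return PairTable(i[order], j[order], shift_arr[order], dist_arr[order], r_cut)


def accumulate_pair_forces(forces: np.ndarray, i: np.ndarray, j: np.ndarray,
                           pair_forces: np.ndarray) -> None:
    """Add +pair_forces to atoms i and −pair_forces to atoms j, in place.

    bincount-based scatter-add; markedly faster than np.add.at for the
    ~10⁵-pair tables the MD loop evaluates every step.
    """
    n = len(forces)
    for ax in range(3):
        forces[:, ax] += np.bincount(i, weights=pair_forces[:, ax], minlength=n)
        forces[:, ax] -= np.bincount(j, weights=pair_forces[:, ax], minlength=n)


def pair_iterator(config: SystemConfiguration, r_cut: float
                  ) -> Iterator[tuple[int, int, np.ndarray, float]]:
    """Stream (i, j, lattice shift, distance) over unique interacting pairs."""
    table = build_pair_table(config, r_cut)
    for k in range(table.count):
        yield int(table.i[k]), int(table.j[k]), table.shift[k], float(table.distance[k])
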