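"""Minimal classical MD over toy force fields.

Supports NVE and NVT (stochastic velocity rescaling) dynamics with a force
field composed of intramolecular harmonic bonds (whose equilibrium lengths
depend on the molecule's charge state), an optional Lennard-Jones term and
one of the two electrostatics methods.  The purpose is validation — energy
conservation with DSF vs Ewald forces, thermal snapshot ensembles, and
finite-temperature reorganization-energy workflows — not performance.

Velocity Verlet with a Verlet neighbour list: the pair table is built with a
skin and rebuilt whenever an atom has moved more than half the skin, so the
evaluated forces are exactly the model's forces at every step (pairs beyond
the cutoff contribute identically zero), preserving energy conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (EnergyForces, InvalidParameterError, StructuralError,
                   SystemConfiguration, accumulate_pair_forces,
                   build_pair_table)
from .dsf import DSFParams, dsf_total
from .ewald import EwaldParams, ewald_total
from .units import AMU_A2_FS2_TO_EV, ATOMIC_MASSES, K_B


@dataclass(frozen=True)
class BondTerm:
    """Intramolecular harmonic bond with state-dependent equilibrium length."""

    atom_a: int
    atom_b: int
    force_constant: float          # eV/Å²
    r0_neutral: float              # Å
    r0_charged: float              # Å

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise InvalidParameterError("bond force constant must be positive")
        if self.r0_neutral <= 0 or self.r0_charged <= 0:
            raise InvalidParameterError("equilibrium bond lengths must be positive")


@dataclass
class LennardJonesTable:
    """Pairwise ε (eV) and σ (Å) per unordered element pair, with a cutoff."""

    epsilon: dict
    sigma: dict
    r_cut: float = 9.0

    def lookup(self, el_a: str, el_b: str) -> tuple[float, float]:
        key = (el_a, el_b) if (el_a, el_b) in self.epsilon else (el_b, el_a)
        eps = self.epsilon.get(key)
        sig = self.sigma.get(key)
        if eps is None or sig is None:
            # Lorentz-Berthelot from the diagonal entries
            ea, sa = self.epsilon[(el_a, el_a)], self.sigma[(el_a, el_a)]
            eb, sb = self.epsilon[(el_b, el_b)], self.sigma[(el_b, el_b)]
            eps, sig = np.sqrt(ea * eb), 0.5 * (sa + sb)
        return float(eps), float(sig)


def bonded_energy_forces(config: SystemConfiguration, bonds: list[BondTerm],
                         state: int | None = None) -> EnergyForces:
    """Σ ½k(r − r⁰)² with r⁰ per the molecule's charge state; analytic forces."""
    state = config.active_state if state is None else state
    pos = config.positions
    forces = np.zeros_like(pos)
    if not bonds:
        return EnergyForces(energy=0.0, forces=forces, components={"bonded": 0.0})
    a = np.array([b.atom_a for b in bonds])
    b_ = np.array([b.atom_b for b in bonds])
    if np.any(config.molecule_index[a] != config.molecule_index[b_]):
        raise StructuralError("bond crosses a molecule boundary")
    k = np.array([b.force_constant for b in bonds])
    charged = config.molecule_index[a] == state
    r0 = np.where(charged,
                  [b.r0_charged for b in bonds],
                  [b.r0_neutral for b in bonds])
    vec = pos[b_] - pos[a]
    r = np.linalg.norm(vec, axis=1)
    energy = float(np.sum(0.5 * k * (r - r0) ** 2))
    f = (k * (r - r0) / r)[:, None] * vec   # on atom_a, toward b if stretched
    np.add.at(forces, a, f)
    np.add.at(forces, b_, -f)
    return EnergyForces(energy=energy, forces=forces, components={"bonded": energy})


class ToyForceField:
    """Bonded + optional LJ + chosen electrostatics, with a reusable pair list."""

    def __init__(self, bonds: list[BondTerm], electrostatics: str = "dsf",
                 params=None, lj: LennardJonesTable | None = None,
                 skin: float = 1.0):
        if electrostatics not in ("dsf", "ewald", "none"):
            raise InvalidParameterError(f"unknown electrostatics {electrostatics!r}")
        self.bonds = bonds
        self.method = electrostatics
        if params is None and electrostatics != "none":
            params = DSFParams() if electrostatics == "dsf" else EwaldParams()
        self.params = params
        self.lj = lj
        self.skin = skin
        self._table = None
        self._lj_table = None
        self._ref_positions = None
        self._lj_coeffs = None
        self._ks = None

    def _elec_r_cut(self) -> float:
        return (self.params.r_cut if self.method == "dsf"
                else self.params.r_cut_real)

    def _refresh_tables(self, config: SystemConfiguration) -> None:
        pos = config.positions
        if self._ref_positions is not None:
            moved = np.linalg.norm(pos - self._ref_positions, axis=1).max()
            if moved < 0.5 * self.skin:
                return
        if self.method != "none":
            self._table = build_pair_table(config, self._elec_r_cut(),
                                           skin=self.skin)
        if self.lj is not None:
            self._lj_table = build_pair_table(config, self.lj.r_cut,
                                              skin=self.skin)
            eps = np.empty(self._lj_table.count)
            sig = np.empty(self._lj_table.count)
            # LJ acts between atoms of different molecules only
            mol_i = config.molecule_index[self._lj_table.i]
            mol_j = config.molecule_index[self._lj_table.j]
            inter = mol_i != mol_j
            for k in range(self._lj_table.count):
                e, s = self.lj.lookup(config.elements[self._lj_table.i[k]],
                                      config.elements[self._lj_table.j[k]])
                eps[k], sig[k] = e, s
            eps[~inter] = 0.0
            self._lj_coeffs = (eps, sig)
        self._ref_positions = pos.copy()

    def _lj_energy_forces(self, config: SystemConfiguration) -> EnergyForces:
        table = self._lj_table
        eps, sig = self._lj_coeffs
        vec = table.vectors(config.positions)
        d = np.linalg.norm(vec, axis=1)
        rc = self.lj.r_cut
        inside = d < rc
        sr6 = np.where(inside, (sig / d) ** 6, 0.0)
        # shifted-force LJ: both energy and force vanish continuously at r_cut
        sr6_cut = (sig / rc) ** 6
        e_cut = 4.0 * eps * (sr6_cut**2 - sr6_cut)
        mag_cut = 24.0 * eps * (2.0 * sr6_cut**2 - sr6_cut) / rc
        e_pair = np.where(inside,
                          4.0 * eps * (sr6**2 - sr6) - e_cut + mag_cut * (d - rc),
                          0.0)
        energy = float(np.sum(e_pair))
        mag = np.where(inside, 24.0 * eps * (2.0 * sr6**2 - sr6) / d - mag_cut, 0.0)
        f = (mag / d)[:, None] * vec
        forces = np.zeros_like(config.positions)
        accumulate_pair_forces(forces, table.j, table.i, f)
        return EnergyForces(energy=energy, forces=forces)

    def evaluate(self, config: SystemConfiguration) -> EnergyForces:
        self._refresh_tables(config)
        res = bonded_energy_forces(config, self.bonds)
        energy, forces = res.energy, res.forces
        components = dict(res.components)
        if self.method == "dsf":
            sub = dsf_total(config, self.params, table=self._table)
            energy += sub.energy
            forces = forces + sub.forces
            components["electrostatic"] = sub.energy
        elif self.method == "ewald":
            if self._ks is None:
                from .ewald import k_vectors
                self._ks = k_vectors(config.cell, self.params.k_max)
            sub = ewald_total(config, self.params, table=self._table, ks=self._ks)
            energy += sub.energy
            forces = forces + sub.forces
            components["electrostatic"] = sub.energy
        if self.lj is not None:
            sub = self._lj_energy_forces(config)
            energy += sub.energy
            forces = forces + sub.forces
            components["lj"] = sub.energy
        return EnergyForces(energy=energy, forces=forces, components=components)


@dataclass
class Trajectory:
    """Frames of an MD run with per-frame energy bookkeeping."""

    times: np.ndarray                 # fs, strictly increasing
    positions: np.ndarray             # (n_frames, N_at, 3)
    velocities: np.ndarray            # (n_frames, N_at, 3) in Å/fs
    potential_energies: np.ndarray    # eV
    kinetic_energies: np.ndarray      # eV
    ensemble: str = "NVE"
    thermostat: dict = field(default_factory=dict)

    @property
    def total_energies(self) -> np.ndarray:
        return self.potential_energies + self.kinetic_energies

    def drift_slope(self, n_atoms: int) -> float:
        """Best-fit total-energy drift in eV·atom⁻¹·ps⁻¹."""
        t_ps = self.times / 1000.0
        slope, _ = np.polyfit(t_ps, self.total_energies / n_atoms, 1)
        return float(slope)

    def kinetic_temperatures(self, n_dof: int) -> np.ndarray:
        return 2.0 * self.kinetic_energies / (n_dof * K_B)


def masses_for(config: SystemConfiguration) -> np.ndarray:
    return np.array([ATOMIC_MASSES[el] for el in config.elements])


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * AMU_A2_FS2_TO_EV * float(np.sum(masses[:, None] * velocities**2))


def velocity_verlet_step(positions: np.ndarray, velocities: np.ndarray,
                         forces: np.ndarray, masses: np.ndarray, dt: float,
                         forces_fn):
    """One velocity-Verlet update; returns (positions, velocities, forces, E_pot)."""
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    acc = forces / (masses[:, None] * AMU_A2_FS2_TO_EV)
    positions = positions + velocities * dt + 0.5 * acc * dt**2
    new = forces_fn(positions)
    if not np.all(np.isfinite(new.forces)):
        raise FloatingPointError("non-finite force encountered during MD step")
    acc_new = new.forces / (masses[:, None] * AMU_A2_FS2_TO_EV)
    velocities = velocities + 0.5 * (acc + acc_new) * dt
    return positions, velocities, new.forces, new.energy


def _csvr_rescale(kin: float, target_kin: float, n_dof: int, dt: float,
                  tau: float, rng: np.random.Generator) -> float:
    """Bussi stochastic-velocity-rescaling factor (canonical sampling)."""
    c = np.exp(-dt / tau)
    r1 = rng.standard_normal()
    # sum of squares of n_dof−1 Gaussians via a gamma draw
    r2 = 2.0 * rng.standard_gamma((n_dof - 1) / 2.0)
    ratio = target_kin / (n_dof * kin)
    alpha2 = (c + (1.0 - c) * ratio * (r1**2 + r2)
              + 2.0 * r1 * np.sqrt(c * (1.0 - c) * ratio))
    return float(np.sqrt(alpha2))


def initial_velocities(config: SystemConfiguration, temperature: float,
                       seed: int = 0) -> np.ndarray:
    """Maxwell-Boltzmann draw with center-of-mass motion removed."""
    rng = np.random.default_rng(seed)
    masses = masses_for(config)
    sigma = np.sqrt(K_B * temperature / (masses * AMU_A2_FS2_TO_EV))
    v = rng.normal(size=(config.n_atoms, 3)) * sigma[:, None]
    v -= np.average(v, axis=0, weights=masses)
    return v


def run_md(config: SystemConfiguration, forcefield: ToyForceField,
           steps: int, dt: float = 1.0, ensemble: str = "NVE",
           temperature: float | None = None, tau_thermostat: float = 100.0,
           velocities: np.ndarray | None = None, seed: int = 0,
           sample_every: int = 1) -> Trajectory:
    """Propagate the system, recording energies every ``sample_every`` steps."""
    if ensemble not in ("NVE", "NVT"):
        raise InvalidParameterError(f"unknown ensemble {ensemble!r}")
    if ensemble == "NVE" and temperature is not None:
        raise InvalidParameterError("a thermostat target makes no sense in NVE")
    if ensemble == "NVT" and temperature is None:
        raise InvalidParameterError("NVT requires a target temperature")
    rng = np.random.default_rng(seed)
    masses = masses_for(config)
    pos = config.positions.copy()
    vel = (np.zeros_like(pos) if velocities is None else velocities.copy())
    current = config

    def forces_fn(p):
        nonlocal current
        current = current.replace_positions(p)
        return forcefield.evaluate(current)

    state = forcefield.evaluate(current)
    forces, epot = state.forces, state.energy
    n_dof = 3 * config.n_atoms - 3

    times, posf, velf, epots, ekins = [], [], [], [], []

    def record(step):
        times.append(step * dt)
        posf.append(pos.copy())
        velf.append(vel.copy())
        epots.append(epot)
        ekins.append(kinetic_energy(vel, masses))

    record(0)
    for step in range(1, steps + 1):
        pos, vel, forces, epot = velocity_verlet_step(
            pos, vel, forces, masses, dt, forces_fn)
        if ensemble == "NVT":
            kin = kinetic_energy(vel, masses)
            if kin > 0:
                target = 0.5 * n_dof * K_B * temperature
                vel = vel * _csvr_rescale(kin, target, n_dof, dt,
                                          tau_thermostat, rng)
        if step % sample_every == 0 or step == steps:
            record(step)
    return Trajectory(times=np.array(times), positions=np.array(posf),
                      velocities=np.array(velf),
                      potential_energies=np.array(epots),
                      kinetic_energies=np.array(ekins), ensemble=ensemble,
                      thermostat=({} if ensemble == "NVE" else
                                  {"type": "stochastic velocity rescaling",
                                   "temperature": temperature,
                                   "tau_fs": tau_thermostat}))


def fluctuation_comparison(configs: list[SystemConfiguration],
                           dsf_params: DSFParams | None = None,
                           ewald_params: EwaldParams | None = None,
                           force_atom: int = 0, force_axis: int = 0) -> dict:
    """Per-snapshot DSF vs Ewald energies and one force component, with metrics.

    Recomputes both electrostatic energies for every configuration, plus the
    chosen atom's force component, and reports standard deviations and
    mean-centered MUE/max error ratios (see ``reorg.error_metrics``).
    """
    from .reorg import error_metrics

    dsf_params = dsf_params or DSFParams()
    ewald_params = ewald_params or EwaldParams()
    e_dsf, e_ew, f_dsf, f_ew = [], [], [], []
    for cfg in configs:
        r_d = dsf_total(cfg, dsf_params)
        r_e = ewald_total(cfg, ewald_params)
        e_dsf.append(r_d.energy)
        e_ew.append(r_e.energy)
        f_dsf.append(r_d.forces[force_atom, force_axis])
        f_ew.append(r_e.forces[force_atom, force_axis])
    e_dsf, e_ew = np.array(e_dsf), np.array(e_ew)
    f_dsf, f_ew = np.array(f_dsf), np.array(f_ew)
    out = {
        "energy_std_dsf": float(np.std(e_dsf, ddof=1)),
        "energy_std_ewald": float(np.std(e_ew, ddof=1)),
        "energy_metrics": error_metrics(e_ew, e_dsf),
        "force_metrics": error_metrics(f_ew, f_dsf),
        "energy_difference": e_dsf - e_ew,
    }
    return out
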