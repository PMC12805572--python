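"""Damped shifted force (DSF) pairwise electrostatics.

The DSF interaction is a purely real-space, pairwise substitute for the full
periodic Coulomb sum: the erfc-damped 1/r kernel is shifted so that both the
potential and its derivative go continuously to zero at the cutoff radius,

    R_DSF(r) = erfc(αr)/r − erfc(αR_c)/R_c
               − [erfc(αR_c)/R_c² + (2α/√π)exp(−α²R_c²)/R_c](R_c − r)

for r < R_c and exactly 0 beyond.  α = 0 recovers the undamped shifted-force
(Wolf-type) limit.  An optional Wolf-style self term
−[erfc(αR_c)/(2R_c) + α/√π]Σq² can be added; it shifts per-state absolute
energies (the charge sets differ between states) but cancels in energy
differences between states of equal composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .core import (EnergyForces, InvalidParameterError, PairTable,
                   SystemConfiguration, accumulate_pair_forces,
                   build_pair_table)
from .units import COULOMB_CONSTANT

SQRT_PI = np.sqrt(np.pi)


@dataclass(frozen=True)
class DSFParams:
    """Damping α (Å⁻¹; 0 = shifted-force limit) and real-space cutoff (Å)."""

    alpha: float = 0.09
    r_cut: float = 16.0
    include_self_term: bool = False

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise InvalidParameterError("r_cut must be positive")
        if self.alpha < 0:
            raise InvalidParameterError("alpha must be non-negative")

    @property
    def energy_shift(self) -> float:
        """erfc(αR_c)/R_c — value of the damped kernel at the cutoff."""
        return float(erfc(self.alpha * self.r_cut) / self.r_cut)

    @property
    def force_shift(self) -> float:
        """erfc(αR_c)/R_c² + (2α/√π)exp(−α²R_c²)/R_c — slope shift at the cutoff."""
        rc, a = self.r_cut, self.alpha
        return float(erfc(a * rc) / rc**2 + (2.0 * a / SQRT_PI) * np.exp(-(a * rc) ** 2) / rc)


def dsf_pair_potential(r, params: DSFParams) -> np.ndarray | float:
    """Unit-charge pair energy k_e·R_DSF(r) in eV·e⁻²; exactly 0 for r ≥ r_cut."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidParameterError("pair distance must be positive")
    inside = r < params.r_cut
    out = np.zeros_like(r)
    rr = np.where(inside, r, params.r_cut)  # dummy to avoid overflow warnings
    val = (erfc(params.alpha * rr) / rr
           - params.energy_shift
           - params.force_shift * (params.r_cut - rr))
    out = np.where(inside, val, 0.0)
    res = COULOMB_CONSTANT * out
    return float(res) if res.ndim == 0 else res


def dsf_pair_force_magnitude(r, params: DSFParams) -> np.ndarray | float:
    """−d/dr of the pair potential (eV·Å⁻¹·e⁻²); 0 at and beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidParameterError("pair distance must be positive")
    inside = r < params.r_cut
    rr = np.where(inside, r, params.r_cut)
    mag = (erfc(params.alpha * rr) / rr**2
           + (2.0 * params.alpha / SQRT_PI) * np.exp(-(params.alpha * rr) ** 2) / rr
           - params.force_shift)
    res = COULOMB_CONSTANT * np.where(inside, mag, 0.0)
    return float(res) if res.ndim == 0 else res


def _dsf_kernels(d: np.ndarray, params: DSFParams, with_forces: bool = True):
    """Pair potential and force magnitude sharing the erfc/exp evaluations."""
    inside = d < params.r_cut
    rr = np.where(inside, d, params.r_cut)
    erfc_r = erfc(params.alpha * rr) / rr
    pot = np.where(inside,
                   erfc_r - params.energy_shift
                   - params.force_shift * (params.r_cut - rr), 0.0)
    mag = None
    if with_forces:
        gauss = (2.0 * params.alpha / SQRT_PI) * np.exp(-(params.alpha * rr) ** 2) / rr
        mag = COULOMB_CONSTANT * np.where(
            inside, erfc_r / rr + gauss - params.force_shift, 0.0)
    return COULOMB_CONSTANT * pot, mag


def dsf_self_energy(config: SystemConfiguration, params: DSFParams) -> float:
    """Wolf-style self term −k_e[erfc(αR_c)/(2R_c) + α/√π]Σq² (optional)."""
    q = config.charges()
    coeff = params.energy_shift / 2.0 + params.alpha / SQRT_PI
    return -COULOMB_CONSTANT * coeff * float(np.sum(q**2))


def dsf_total(config: SystemConfiguration, params: DSFParams | None = None,
              table: PairTable | None = None, with_forces: bool = True) -> EnergyForces:
    """DSF energy and forces over all pairs within r_cut (explicit images)."""
    params = params or DSFParams()
    if table is None:
        table = build_pair_table(config, params.r_cut)
    q = config.charges()
    forces = np.zeros_like(config.positions)
    if table.count:
        # distances from *current* positions: the table may be a cached
        # neighbour list built with a skin at earlier positions
        vec = table.vectors(config.positions)
        d = np.linalg.norm(vec, axis=1)
        qq = q[table.i] * q[table.j]
        pot, mag = _dsf_kernels(d, params, with_forces)
        energy = float(np.sum(qq * pot))
        if with_forces:
            f = (qq * mag / d)[:, None] * vec
            accumulate_pair_forces(forces, table.j, table.i, f)
    else:
        energy = 0.0
    components = {"real": energy}
    if params.include_self_term:
        e_self = dsf_self_energy(config, params)
        components["self"] = e_self
        energy += e_self
    return EnergyForces(energy=energy, forces=forces, components=components)
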