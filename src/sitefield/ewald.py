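"""Direct (non-mesh) Ewald summation under tinfoil boundary conditions.

The conditionally convergent Coulomb lattice sum is split into a
short-ranged real-space part with kernel erfc(η r)/r, a smooth
reciprocal-space sum over vectors 0 < |k| ≤ k_max, and a position
independent self term −(η/√π)Σq².  For a cell with net charge q a uniform
neutralizing background contributes the additional constant
−q²π/(2η²V).  This module is deliberately simple and fully converged —
it is the exact oracle against which the damped-shifted-force method and
the multistate addition-subtraction scheme are validated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .core import (EnergyForces, InvalidParameterError, PairTable,
                   SystemConfiguration, accumulate_pair_forces,
                   build_pair_table)
from .units import COULOMB_CONSTANT

SQRT_PI = np.sqrt(np.pi)


@dataclass(frozen=True)
class EwaldParams:
    """Convergence parameters: η (Å⁻¹), real-space cutoff (Å), k_max (Å⁻¹)."""

    eta: float = 0.35
    r_cut_real: float = 9.6
    k_max: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.r_cut_real <= 0 or self.k_max <= 0:
            raise InvalidParameterError("Ewald parameters must be strictly positive")


def converged_params(eta: float = 0.35, accuracy: float = 1e-9) -> EwaldParams:
    """Cutoffs that make both partial sums converged at the given kernel decay.

    Real space: erfc(η r)/r ≲ accuracy; reciprocal: exp(−k²/4η²) ≲ accuracy.
    Used where the exact (η-independent) Ewald value is required, e.g. when
    validating against literature lattice constants.
    """
    x = float(np.sqrt(max(-np.log(accuracy), 1.0)))  # erfc(x) ≈ e^{−x²}, same decay
    return EwaldParams(eta=eta, r_cut_real=(x + 0.8) / eta,
                       k_max=2.0 * eta * (x + 0.8))


def real_space_kernel(r: np.ndarray, eta: float) -> np.ndarray:
    """erfc(η r)/r — the short-ranged real-space interaction."""
    r = np.asarray(r, dtype=float)
    return erfc(eta * r) / r


def real_space_kernel_derivative_magnitude(r: np.ndarray, eta: float) -> np.ndarray:
    """|d/dr| of erfc(η r)/r, i.e. erfc(ηr)/r² + (2η/√π)exp(−η²r²)/r."""
    r = np.asarray(r, dtype=float)
    return erfc(eta * r) / r**2 + (2.0 * eta / SQRT_PI) * np.exp(-(eta * r) ** 2) / r


def k_vectors(cell, k_max: float) -> np.ndarray:
    """All reciprocal vectors with 0 < |k| ≤ k_max (full set, no halving)."""
    recip = cell.reciprocal_vectors
    bounds = np.ceil(k_max / (2.0 * np.pi / np.linalg.norm(cell.lattice_vectors, axis=1))).astype(int)
    # conservative integer bounds from row norms of the reciprocal matrix
    bounds = np.maximum(bounds, np.ceil(k_max / np.linalg.norm(recip, axis=1)).astype(int))
    ms = np.array(list(itertools.product(*[range(-b, b + 1) for b in bounds])))
    ks = ms @ recip
    mags = np.linalg.norm(ks, axis=1)
    keep = (mags > 1e-12) & (mags <= k_max)
    return ks[keep]


def ewald_real_energy(config: SystemConfiguration, params: EwaldParams,
                      table: PairTable | None = None) -> float:
    q = config.charges()
    if table is None:
        table = build_pair_table(config, params.r_cut_real)
    if table.count == 0:
        return 0.0
    kern = real_space_kernel(table.distances(config.positions), params.eta)
    return COULOMB_CONSTANT * float(np.sum(q[table.i] * q[table.j] * kern))


def ewald_reciprocal_energy(config: SystemConfiguration, params: EwaldParams,
                            ks: np.ndarray | None = None) -> float:
    q = config.charges()
    if ks is None:
        ks = k_vectors(config.cell, params.k_max)
    if len(ks) == 0:
        warnings.warn("k_max admits no reciprocal vectors; reciprocal energy = 0")
        return 0.0
    k2 = np.sum(ks**2, axis=1)
    phase = ks @ config.positions.T           # (N_k, N_at)
    s = np.exp(1j * phase) @ q                # structure factor per k
    coeff = np.exp(-k2 / (4.0 * params.eta**2)) / k2
    pref = 2.0 * np.pi / config.cell.volume
    return COULOMB_CONSTANT * pref * float(np.sum(coeff * np.abs(s) ** 2))


def ewald_self_energy(config: SystemConfiguration, params: EwaldParams) -> float:
    q = config.charges()
    return -COULOMB_CONSTANT * params.eta / SQRT_PI * float(np.sum(q**2))


def ewald_background_correction(config: SystemConfiguration, params: EwaldParams) -> float:
    """Constant −q²π/(2η²V) compensating the implicit neutralizing background."""
    q_tot = config.total_charge()
    if q_tot == 0.0:
        return 0.0
    return -COULOMB_CONSTANT * q_tot**2 * np.pi / (2.0 * params.eta**2 * config.cell.volume)


def ewald_real_forces(config: SystemConfiguration, params: EwaldParams,
                      table: PairTable | None = None) -> np.ndarray:
    q = config.charges()
    forces = np.zeros_like(config.positions)
    if table is None:
        table = build_pair_table(config, params.r_cut_real)
    if table.count == 0:
        return forces
    vec = table.vectors(config.positions)
    d = np.linalg.norm(vec, axis=1)
    mag = real_space_kernel_derivative_magnitude(d, params.eta)
    # for like charges the force on i points along −(R_j+n−R_i), away from j
    f = (COULOMB_CONSTANT * q[table.i] * q[table.j] * mag / d)[:, None] * vec
    accumulate_pair_forces(forces, table.j, table.i, f)
    return forces


def ewald_reciprocal_forces(config: SystemConfiguration, params: EwaldParams,
                            ks: np.ndarray | None = None) -> np.ndarray:
    """Analytic derivative of the reciprocal sum in structure-factor form.

    F_j = k_e (4π/V) Σ_k (exp(−k²/4η²)/k²) q_j k Im[e^{ik·R_j} S*(k)],
    evaluated at cost O(N_k N_at).
    """
    q = config.charges()
    if ks is None:
        ks = k_vectors(config.cell, params.k_max)
    if len(ks) == 0:
        return np.zeros_like(config.positions)
    k2 = np.sum(ks**2, axis=1)
    coeff = np.exp(-k2 / (4.0 * params.eta**2)) / k2
    phase = np.exp(1j * (ks @ config.positions.T))   # (N_k, N_at)
    s = phase @ q
    weight = coeff[:, None] * np.imag(phase * np.conj(s)[:, None])  # (N_k, N_at)
    pref = COULOMB_CONSTANT * 4.0 * np.pi / config.cell.volume
    return pref * q[:, None] * (weight.T @ ks)


def ewald_total(config: SystemConfiguration, params: EwaldParams | None = None,
                with_forces: bool = True, table: PairTable | None = None,
                ks: np.ndarray | None = None) -> EnergyForces:
    """Total Ewald energy (real + reciprocal + self + background) and forces.

    ``table``/``ks`` allow reuse of a cached neighbour list (possibly built
    with a skin) and k-vector set; distances are always taken from the
    current positions.
    """
    params = params or EwaldParams()
    if table is None:
        table = build_pair_table(config, params.r_cut_real)
    if ks is None:
        ks = k_vectors(config.cell, params.k_max)
    e_real = ewald_real_energy(config, params, table)
    e_rec = ewald_reciprocal_energy(config, params, ks)
    e_self = ewald_self_energy(config, params)
    e_bg = ewald_background_correction(config, params)
    forces = None
    if with_forces:
        forces = ewald_real_forces(config, params, table)
        forces += ewald_reciprocal_forces(config, params, ks)
    else:
        forces = np.zeros_like(config.positions)
    return EnergyForces(
        energy=e_real + e_rec + e_self + e_bg,
        forces=forces,
        components={"real": e_real, "reciprocal": e_rec,
                    "self": e_self, "background": e_bg},
    )
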