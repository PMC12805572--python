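"""Reorganization-energy estimators, Marcus continuum theory and benchmarks.

The reorganization energy λ for charge transfer between two equivalent
molecules can be estimated three ways from classical simulation:

* Stokes-shift estimator λ^st = ⟨ΔE⟩_A — the mean vertical energy gap
  sampled on the initial-state surface (the driving force is zero for
  self-exchange between equivalent sites);
* variance estimator λ^var = σ_A²/(2 k_B T) — from the gap fluctuations;
  λ^st = λ^var exactly in the linear-response limit, so their agreement is
  a linear-response diagnostic;
* 4-point estimator λ^4p = [E_A(R_B) + E_B(R_A)] − [E_B(R_B) + E_A(R_A)]
  from the minimized end-state geometries — the T → 0 limit of λ^st.

λ splits into an inner-sphere (intramolecular) part λ_i and an outer-sphere
(environment) part λ_o = λ − λ_i.  Marcus' continuum expression for λ_o and
the Pekar-factor ratio quantify how electronic polarizability (optical
dielectric constant ε_op) screens the outer-sphere contribution; the
charge-scaling factor γ = ε_op^(−1/2) mimics that screening in a fixed
point-charge force field.

The module also houses the MUE/MUF error metrics used for benchmarking the
damped-shifted-force method against Ewald summation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import InvalidParameterError, MoleculeChargeSpec
from .units import COULOMB_CONSTANT, K_B


@dataclass
class GapSeries:
    """Vertical energy gap ΔE = E_B − E_A time series (eV) at temperature T."""

    gaps: np.ndarray
    temperature: float
    sampling_interval_fs: float = 1000.0

    def __post_init__(self) -> None:
        self.gaps = np.asarray(self.gaps, dtype=float)
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")
        if self.gaps.ndim != 1 or len(self.gaps) < 1:
            raise InvalidParameterError("gap series must be a non-empty 1-D array")


@dataclass
class ReorgResult:
    lambda_stokes: float
    lambda_stokes_error: float
    lambda_variance: float
    lambda_four_point: float | None = None
    lambda_inner: float | None = None
    lambda_outer: float | None = None


def lambda_stokes(series: GapSeries, n_blocks: int = 5) -> tuple[float, float]:
    """Mean gap with block-averaged statistical error (n_blocks equal blocks)."""
    gaps = series.gaps
    if len(gaps) == 0:
        raise InvalidParameterError("empty gap series")
    mean = float(np.mean(gaps))
    if len(gaps) < n_blocks:
        return mean, float("nan")
    usable = (len(gaps) // n_blocks) * n_blocks
    block_means = gaps[:usable].reshape(n_blocks, -1).mean(axis=1)
    err = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    return mean, err


def lambda_variance(series: GapSeries) -> float:
    """σ_A²/(2 k_B T) with the sample (n−1) variance."""
    if len(series.gaps) < 2:
        raise InvalidParameterError("variance estimator needs at least 2 samples")
    sigma2 = float(np.var(series.gaps, ddof=1))
    return sigma2 / (2.0 * K_B * series.temperature)


def lambda_four_point(e_a_at_ra: float, e_b_at_ra: float,
                      e_a_at_rb: float, e_b_at_rb: float) -> float:
    """[E_A(R_B) + E_B(R_A)] − [E_B(R_B) + E_A(R_A)]."""
    vals = (e_a_at_ra, e_b_at_ra, e_a_at_rb, e_b_at_rb)
    if not all(np.isfinite(vals)):
        raise InvalidParameterError("4-point energies must be finite")
    return (e_a_at_rb + e_b_at_ra) - (e_b_at_rb + e_a_at_ra)


def split_inner_outer(lambda_total: float, lambda_inner: float) -> float:
    """Outer-sphere contribution λ_o = λ − λ_i.

    Uses the convention λ_i^st ≈ λ_i^4p (the small temperature dependence of
    the inner-sphere contribution is neglected).
    """
    if not (np.isfinite(lambda_total) and np.isfinite(lambda_inner)):
        raise InvalidParameterError("inputs must be finite")
    return lambda_total - lambda_inner


@dataclass(frozen=True)
class DielectricParams:
    """Continuum-model inputs: dielectric constants, cavity radii, ET distance."""

    eps_optical: float
    eps_static: float
    r_donor: float
    r_acceptor: float
    distance: float
    delta_charge: float = 1.0

    def __post_init__(self) -> None:
        if not (self.eps_static >= self.eps_optical >= 1.0):
            raise InvalidParameterError("require ε_s ≥ ε_op ≥ 1")
        if min(self.r_donor, self.r_acceptor, self.distance) <= 0:
            raise InvalidParameterError("radii and transfer distance must be positive")


def marcus_continuum(params: DielectricParams) -> float:
    """Marcus outer-sphere λ_o (eV): (Δq)²(1/ε_op − 1/ε_s)(1/2r_D + 1/2r_A − 1/R)."""
    pekar = 1.0 / params.eps_optical - 1.0 / params.eps_static
    geom = (0.5 / params.r_donor + 0.5 / params.r_acceptor - 1.0 / params.distance)
    return COULOMB_CONSTANT * params.delta_charge**2 * pekar * geom


def pekar_ratio(eps_optical: float, eps_static: float) -> float:
    """(1 − 1/ε_s)/(1/ε_op − 1/ε_s): outer-sphere λ of the nonpolarizable
    description (ε_op → 1) over that of the polarizable one."""
    if eps_optical < 1.0:
        raise InvalidParameterError("ε_op must be ≥ 1")
    if eps_static <= eps_optical:
        raise InvalidParameterError("ratio undefined for ε_s ≤ ε_op")
    return (1.0 - 1.0 / eps_static) / (1.0 / eps_optical - 1.0 / eps_static)


def charge_scale_factor(eps_optical: float) -> float:
    """γ = ε_op^(−1/2), the charge scaling emulating electronic screening."""
    if eps_optical < 1.0:
        raise InvalidParameterError("ε_op must be ≥ 1")
    return eps_optical ** -0.5


@dataclass(frozen=True)
class ChargeStateBuilder:
    """Reference charge/bond increments for building the charged-state force field.

    ``delta_charges`` are the per-atom charge differences between the charged
    and neutral molecule (summing to the net charge q); ``delta_bonds`` the
    per-bond equilibrium-length changes.  β scales the bond displacements
    (default 0.88) and γ scales the neutral charges (1.0 = no screening).
    """

    delta_charges: np.ndarray
    delta_bonds: np.ndarray | None = None
    beta: float = 0.88
    gamma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_charges",
                           np.asarray(self.delta_charges, dtype=float))
        if self.delta_bonds is not None:
            object.__setattr__(self, "delta_bonds",
                               np.asarray(self.delta_bonds, dtype=float))
        if not (0.0 < self.beta <= 1.5) or not (0.0 < self.gamma <= 1.5):
            raise InvalidParameterError("β and γ must lie in (0, 1.5]")


def apply_charge_scaling(spec: MoleculeChargeSpec,
                         builder: ChargeStateBuilder) -> MoleculeChargeSpec:
    """Scaled charge sets: q̃^n = γ q^n and q̃^c = γ q^n + Δq.

    Because Σq^n = 0 and ΣΔq = q, the scaled charged molecule keeps net
    charge exactly q for any γ.
    """
    dq = builder.delta_charges
    if len(dq) != spec.n_atoms_per_molecule:
        raise InvalidParameterError("delta_charges length mismatch")
    if abs(dq.sum() - spec.net_charge) > 1e-9:
        raise InvalidParameterError(
            f"ΣΔq = {dq.sum():.6f} must equal the net charge {spec.net_charge}")
    qn = builder.gamma * spec.neutral_charges
    return MoleculeChargeSpec(neutral_charges=qn, charged_charges=qn + dq,
                              net_charge=spec.net_charge)


def build_charged_state_bonds(bonds, builder: ChargeStateBuilder):
    """Per-bond charged equilibrium lengths r⁰c = r⁰n + β·Δr."""
    if builder.delta_bonds is None or len(builder.delta_bonds) != len(bonds):
        raise InvalidParameterError("delta_bonds must align with the bond list")
    return [replace(b, r0_charged=b.r0_neutral + builder.beta * dr)
            for b, dr in zip(bonds, builder.delta_bonds)]


def error_metrics(reference: np.ndarray, test: np.ndarray,
                  center: bool = True) -> dict:
    """MUE/MUF and max/MUF of a test series against a reference, as percentages.

    MUF is the mean unsigned fluctuation of the reference about its own mean.
    With ``center=True`` (default) both series are first centered on their own
    means, so the metric measures fluctuation error rather than any constant
    offset between the two summation methods.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape or len(reference) < 2:
        raise InvalidParameterError("series must have equal length ≥ 2")
    muf = float(np.mean(np.abs(reference - reference.mean())))
    if muf == 0.0:
        raise InvalidParameterError("reference series has zero fluctuation; "
                                    "MUE/MUF normalization undefined")
    diff = ((test - test.mean()) - (reference - reference.mean())
            if center else test - reference)
    mue = float(np.mean(np.abs(diff)))
    mx = float(np.max(np.abs(diff)))
    return {"mue": mue, "muf": muf, "max": mx,
            "mue_over_muf_percent": 100.0 * mue / muf,
            "max_over_muf_percent": 100.0 * mx / muf}


def mobility_anisotropy(mu_b: float, mu_a: float) -> float:
    """Mobility anisotropy μ_b/μ_a."""
    if mu_a <= 0:
        raise InvalidParameterError("μ_a must be positive")
    return mu_b / mu_a
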