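"""Site-basis charge-carrier propagation and transport observables.

The carrier is expanded in charge-localized molecular (site) states,
Ψ(t) = Σ_k u_k(t) φ_k, with a tight-binding Hamiltonian
H = Σ_k ε_k |φ_k⟩⟨φ_k| + Σ_{k≠l} H_kl |φ_k⟩⟨φ_l| whose site energies and
couplings fluctuate along a (supplied) nuclear trajectory.  The coefficients
obey iħ u̇_k = Σ_l u_l H_kl in the strictly diabatic mode used here: the
nonadiabatic couplings d_kl stem from nuclear motion of the orbital basis,
which this module does not model — it operates on given H(t) and documents
the approximation.  Propagation is classic RK4 with an electronic substep
δt = Δt/substeps and linear interpolation of H between frames.

Observables: the inverse participation ratio IPR = 1/Σ|u_k|⁴ (number of
sites the carrier spans), the mean-squared-displacement tensor
MSD_αβ(t) = ⟨Σ_k P_k (α_k−α_0)(β_k−β_0)⟩ over trajectories, the diffusion
tensor D = ½ d(MSD)/dt and the Einstein mobility μ = eD/k_BT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import HBAR, K_B

#: Å²/fs → cm²/s
A2_PER_FS_TO_CM2_PER_S = 1e-16 / 1e-15


@dataclass
class SiteHamiltonianTrajectory:
    """ε_k(t) (eV), couplings H_kl(t) (symmetric, zero diagonal) and site positions."""

    times: np.ndarray                 # (n_frames,) fs
    site_energies: np.ndarray         # (n_frames, N)
    couplings: np.ndarray             # (n_frames, N, N)
    site_positions: np.ndarray        # (N, 3) Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.site_energies = np.atleast_2d(np.asarray(self.site_energies, float))
        self.couplings = np.asarray(self.couplings, dtype=float)
        n_frames, n_sites = self.site_energies.shape
        if self.couplings.shape != (n_frames, n_sites, n_sites):
            raise ValueError("couplings shape inconsistent with site energies")
        if not np.allclose(self.couplings, np.swapaxes(self.couplings, 1, 2),
                           atol=1e-12):
            raise ValueError("coupling matrices must be symmetric")
        if np.any(np.abs(np.diagonal(self.couplings, axis1=1, axis2=2)) > 1e-12):
            raise ValueError("coupling matrices must have zero diagonal")

    @property
    def n_sites(self) -> int:
        return self.site_energies.shape[1]

    @property
    def n_frames(self) -> int:
        return self.site_energies.shape[0]

    def hamiltonian(self, frame: int) -> np.ndarray:
        h = self.couplings[frame].copy()
        h[np.diag_indices(self.n_sites)] = self.site_energies[frame]
        return h

    def interpolated(self, t: float) -> np.ndarray:
        """H(t) linearly interpolated between stored frames."""
        times = self.times
        if t <= times[0]:
            return self.hamiltonian(0)
        if t >= times[-1]:
            return self.hamiltonian(self.n_frames - 1)
        idx = int(np.searchsorted(times, t) - 1)
        w = (t - times[idx]) / (times[idx + 1] - times[idx])
        return (1.0 - w) * self.hamiltonian(idx) + w * self.hamiltonian(idx + 1)


def _check_normalized(psi: np.ndarray, tol: float = 1e-8) -> None:
    norm = float(np.sum(np.abs(psi) ** 2))
    if abs(norm - 1.0) > tol:
        raise ValueError(f"wavefunction not normalized: Σ|u|² = {norm}")


def propagate_wavefunction(h_traj: SiteHamiltonianTrajectory, psi0: np.ndarray,
                           dt_nuclear: float | None = None, substeps: int = 5
                           ) -> np.ndarray:
    """RK4 integration of iħ u̇ = H(t) u over the trajectory's time grid.

    Returns coefficients at every nuclear frame, shape (n_frames, N).
    The electronic step is dt_nuclear/substeps; norm is monitored, never
    silently renormalized.
    """
    psi = np.asarray(psi0, dtype=complex)
    _check_normalized(psi)
    if substeps < 1:
        raise ValueError("substeps must be ≥ 1")
    times = h_traj.times
    if dt_nuclear is None:
        dt_nuclear = float(times[1] - times[0]) if len(times) > 1 else 1.0
    out = np.empty((h_traj.n_frames, h_traj.n_sites), dtype=complex)
    out[0] = psi

    def deriv(t, u):
        h = h_traj.interpolated(t)
        return (-1j / HBAR) * (h @ u)

    dt_e = dt_nuclear / substeps
    for frame in range(1, h_traj.n_frames):
        t = times[frame - 1]
        for _ in range(substeps):
            k1 = deriv(t, psi)
            k2 = deriv(t + dt_e / 2, psi + dt_e * k1 / 2)
            k3 = deriv(t + dt_e / 2, psi + dt_e * k2 / 2)
            k4 = deriv(t + dt_e, psi + dt_e * k3)
            psi = psi + dt_e * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            t += dt_e
        out[frame] = psi
    return out


def fewest_switches_probabilities(h_prev: np.ndarray, h_next: np.ndarray,
                                  psi_adiabatic: np.ndarray, active: int,
                                  dt: float) -> np.ndarray:
    """Tully fewest-switches hop probabilities from the active adiabatic state.

    The time-derivative couplings T_jl = ⟨φ_j|φ̇_l⟩ are estimated from the
    overlap of the eigenvector bases of two consecutive frames; degenerate
    eigenvalues are ordered by eigenvalue then by largest-amplitude site
    index, and eigenvector signs fixed so the diagonal overlap is positive.
    Probabilities are clipped to [0, 1].
    """
    _, v_prev = _sorted_eigh(h_prev)
    _, v_next = _sorted_eigh(h_next)
    overlap = v_prev.T @ v_next
    signs = np.sign(np.diag(overlap))
    signs[signs == 0] = 1.0
    v_next = v_next * signs[None, :]
    overlap = overlap * signs[None, :]
    t_mat = (overlap - overlap.T) / (2.0 * dt)   # antisymmetric ⟨φ_j|φ̇_l⟩
    a_pop = np.abs(psi_adiabatic[active]) ** 2
    if a_pop < 1e-12:
        return np.zeros(len(psi_adiabatic))
    # b_la = −2 Re(a*_la T_la), flux from active a into l
    b = -2.0 * np.real(np.conj(psi_adiabatic) * psi_adiabatic[active]
                       * t_mat[:, active])
    g = dt * b / a_pop
    g[active] = 0.0
    return np.clip(g, 0.0, 1.0)


def _sorted_eigh(h: np.ndarray):
    vals, vecs = np.linalg.eigh(h)
    order = np.lexsort((np.argmax(np.abs(vecs), axis=0), np.round(vals, 12)))
    return vals[order], vecs[:, order]


def surface_hop_step(h_prev: np.ndarray, h_next: np.ndarray, psi: np.ndarray,
                     active_state: int, dt: float,
                     rng: np.random.Generator) -> int:
    """One fewest-switches hopping decision; hops are accepted as drawn.

    ``psi`` is in the site basis; it is rotated to the adiabatic basis of
    ``h_prev``.  No velocity adjustment is applied (no nuclear back-reaction
    in this model mode).
    """
    _, v = _sorted_eigh(h_prev)
    psi_ad = v.T @ psi
    g = fewest_switches_probabilities(h_prev, h_next, psi_ad, active_state, dt)
    xi = rng.random()
    cumulative = 0.0
    for state, prob in enumerate(g):
        cumulative += prob
        if xi < cumulative:
            return state
    return active_state


@dataclass
class TransportObservables:
    """IPR(t), MSD tensor (Å²), diffusion (cm²/s) and mobility (cm²/V/s)."""

    times: np.ndarray
    ipr: np.ndarray
    msd: np.ndarray                   # (n_frames, 3, 3)
    diffusion: np.ndarray | None = None
    mobility: np.ndarray | None = None
    n_trajectories: int = 1
    extras: dict = field(default_factory=dict)


def ipr(psi_series: np.ndarray, n_trajectories: int = 1) -> np.ndarray:
    """Mean inverse participation ratio 1/Σ_k|u_k|⁴ over trajectories.

    ``psi_series`` has shape (n_traj, n_frames, N) or (n_frames, N).
    """
    psi = np.asarray(psi_series)
    if psi.ndim == 2:
        psi = psi[None, ...]
    pops = np.abs(psi) ** 2
    norms = pops.sum(axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("IPR requires normalized coefficients")
    return np.mean(1.0 / np.sum(pops**2, axis=-1), axis=0)


def msd_tensor(psi_series: np.ndarray, site_positions: np.ndarray,
               origin: np.ndarray | None = None) -> np.ndarray:
    """MSD_αβ(t) = ⟨Σ_k P_k (α_k − α_0)(β_k − β_0)⟩ in Å².

    The origin defaults to the initial expectation position of each
    trajectory.  Returns shape (n_frames, 3, 3); symmetric, diagonal ≥ 0.
    """
    psi = np.asarray(psi_series)
    if psi.ndim == 2:
        psi = psi[None, ...]
    pops = np.abs(psi) ** 2                     # (n_traj, n_frames, N)
    pos = np.asarray(site_positions, float)     # (N, 3)
    if pos.shape[0] != psi.shape[-1]:
        raise ValueError("site_positions inconsistent with coefficients")
    msd = np.zeros((psi.shape[1], 3, 3))
    for n in range(psi.shape[0]):
        x0 = (pops[n, 0] @ pos) if origin is None else np.asarray(origin, float)
        dx = pos - x0                            # (N, 3)
        # Σ_k P_k dx_α dx_β per frame
        msd += np.einsum("tk,ka,kb->tab", pops[n], dx, dx)
    return msd / psi.shape[0]


def diffusion_from_msd(times: np.ndarray, msd_series: np.ndarray,
                       fit_fraction: float = 0.8) -> np.ndarray:
    """D_αβ = ½ · slope of the MSD over the trailing fit window, in cm²/s.

    The leading (1 − fit_fraction) of the series is discarded before the
    linear fit (default: first 20%).
    """
    times = np.asarray(times, float)
    msd_series = np.asarray(msd_series, float)
    n = len(times)
    start = int(np.floor((1.0 - fit_fraction) * n))
    if n - start < 2:
        raise ValueError("fit window shorter than 2 points")
    t = times[start:]
    d = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            y = msd_series[start:, a, b]
            if np.allclose(y, y[0]):
                if a == b and np.any(msd_series[:, a, a] != 0):
                    warnings.warn("constant MSD component; D set to 0")
                continue
            slope, _ = np.polyfit(t, y, 1)
            d[a, b] = 0.5 * slope
    return d * A2_PER_FS_TO_CM2_PER_S


def mobility_from_diffusion(diffusion: np.ndarray, temperature: float) -> np.ndarray:
    """Einstein relation μ_αβ = e D_αβ / (k_B T), element-wise."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return np.asarray(diffusion) / (K_B * temperature)


def transport_observables(h_traj: SiteHamiltonianTrajectory,
                          psi0: np.ndarray | None = None, n_trajectories: int = 1,
                          substeps: int = 5, temperature: float = 300.0,
                          seed: int = 0, fit_fraction: float = 0.8,
                          trajectory_factory=None) -> TransportObservables:
    """Propagate one or many trajectories and collect all transport observables.

    ``trajectory_factory(seed_index)`` may supply a fresh Hamiltonian
    trajectory per run (e.g. re-seeded site-energy noise); otherwise the same
    H(t) is reused and only ``psi0`` defines the ensemble.
    """
    n_sites = h_traj.n_sites
    if psi0 is None:
        psi0 = np.zeros(n_sites, dtype=complex)
        psi0[n_sites // 2] = 1.0
    runs = []
    for n in range(n_trajectories):
        traj = h_traj if trajectory_factory is None else trajectory_factory(seed + n)
        runs.append(propagate_wavefunction(traj, psi0, substeps=substeps))
    psi_series = np.array(runs)
    ipr_t = ipr(psi_series, n_trajectories)
    msd_t = msd_tensor(psi_series, h_traj.site_positions)
    diff = diffusion_from_msd(h_traj.times, msd_t, fit_fraction=fit_fraction)
    mob = mobility_from_diffusion(diff, temperature)
    return TransportObservables(times=h_traj.times, ipr=ipr_t, msd=msd_t,
                                diffusion=diff, mobility=mob,
                                n_trajectories=n_trajectories)
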