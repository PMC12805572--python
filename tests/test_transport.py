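"""Wavefunction propagation, surface hopping and transport observables."""

import numpy as np
import pytest

from sitefield.fixtures import make_hamiltonian_chain
from sitefield.transport import (SiteHamiltonianTrajectory, _sorted_eigh,
                                 diffusion_from_msd,
                                 fewest_switches_probabilities, ipr,
                                 mobility_from_diffusion, msd_tensor,
                                 propagate_wavefunction, surface_hop_step,
                                 transport_observables)
from sitefield.units import HBAR


def static_two_site(J, n_frames=200, dt=0.5, eps=None):
    e = np.zeros((n_frames, 2)) if eps is None else np.tile(eps, (n_frames, 1))
    return SiteHamiltonianTrajectory(
        times=np.arange(n_frames) * dt, site_energies=e,
        couplings=np.broadcast_to(np.array([[0.0, J], [J, 0.0]]),
                                  (n_frames, 2, 2)).copy(),
        site_positions=np.array([[0.0, 0, 0], [5.0, 0, 0]]))


class TestPropagation:
    def test_rabi_oscillation_closed_form(self):
        J = 0.02
        traj = static_two_site(J)
        psi = propagate_wavefunction(traj, np.array([1, 0], complex), substeps=5)
        expected = np.sin(J * traj.times / HBAR) ** 2
        assert np.abs(np.abs(psi[:, 1]) ** 2 - expected).max() < 1e-6

    def test_rabi_full_transfer_time(self):
        J = 0.02
        t_half = np.pi * HBAR / (2 * J)
        dt = t_half / 100
        traj = static_two_site(J, n_frames=101, dt=dt)
        psi = propagate_wavefunction(traj, np.array([1, 0], complex), substeps=5)
        assert np.abs(psi[-1, 1]) ** 2 == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_hamiltonian_constant_populations(self):
        n = 4
        eps = np.array([0.1, -0.05, 0.2, 0.0])
        traj = SiteHamiltonianTrajectory(
            times=np.arange(50) * 1.0, site_energies=np.tile(eps, (50, 1)),
            couplings=np.zeros((50, n, n)), site_positions=np.zeros((n, 3)))
        psi0 = np.ones(n, complex) / 2.0
        psi = propagate_wavefunction(traj, psi0, substeps=5)
        assert np.abs(np.abs(psi) ** 2 - 0.25).max() < 1e-7
        # phases evolve as e^{−iε t/ħ} (RK4 phase error is 5th order in δt)
        expected = psi0 * np.exp(-1j * eps * traj.times[-1] / HBAR)
        assert np.abs(psi[-1] - expected).max() < 1e-6

    def test_norm_conserved_on_random_hamiltonian(self):
        # site-energy and coupling scales typical of molecular semiconductors
        # (tens of meV); the RK4 norm error grows as (|H| δt/ħ)⁶ per substep
        rng = np.random.default_rng(5)
        n_frames, n = 1000, 6
        eps = rng.normal(0, 0.015, (n_frames, n))
        base = rng.normal(0, 0.005, (n, n))
        off = (base + base.T) / 2
        np.fill_diagonal(off, 0.0)
        traj = SiteHamiltonianTrajectory(
            times=np.arange(n_frames) * 1.0, site_energies=eps,
            couplings=np.broadcast_to(off, (n_frames, n, n)).copy(),
            site_positions=rng.normal(0, 5, (n, 3)))
        psi0 = np.zeros(n, complex)
        psi0[0] = 1.0
        psi = propagate_wavefunction(traj, psi0, substeps=5)   # 1 ps
        norms = (np.abs(psi) ** 2).sum(axis=1)
        assert np.abs(norms - 1.0).max() < 1e-8

    def test_substep_convergence(self):
        traj = make_hamiltonian_chain(10, 0.02, 0.03, 50.0, 1.0, 200, seed=2)
        psi0 = np.zeros(10, complex)
        psi0[5] = 1.0
        p5 = np.abs(propagate_wavefunction(traj, psi0, substeps=5)) ** 2
        p10 = np.abs(propagate_wavefunction(traj, psi0, substeps=10)) ** 2
        assert np.abs(p5 - p10).max() < 1e-8

    def test_unnormalized_input_rejected(self):
        traj = static_two_site(0.01, n_frames=3)
        with pytest.raises(ValueError, match="not normalized"):
            propagate_wavefunction(traj, np.array([1.0, 1.0], complex))

    def test_asymmetric_coupling_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SiteHamiltonianTrajectory(
                times=np.array([0.0]), site_energies=np.zeros((1, 2)),
                couplings=np.array([[[0.0, 0.1], [0.2, 0.0]]]),
                site_positions=np.zeros((2, 3)))


class TestSurfaceHopping:
    def test_static_hamiltonian_never_hops(self):
        traj = static_two_site(0.02, eps=np.array([0.0, 0.1]))
        psi = propagate_wavefunction(traj, np.array([1, 0], complex))
        rng = np.random.default_rng(0)
        active = 0
        for f in range(traj.n_frames - 1):
            active = surface_hop_step(traj.hamiltonian(f), traj.hamiltonian(f + 1),
                                      psi[f], active, 0.5, rng)
        assert active == 0

    def test_probabilities_clipped(self):
        h0 = np.array([[0.0, 0.01], [0.01, 0.05]])
        h1 = np.array([[0.05, 0.01], [0.01, 0.0]])
        psi_ad = np.array([0.8 + 0j, 0.6 + 0j])
        g = fewest_switches_probabilities(h0, h1, psi_ad, 0, 1000.0)
        assert np.all(g >= 0.0) and np.all(g <= 1.0)

    def test_hop_statistics_match_deterministic_oracle(self):
        """Monte-Carlo hop fraction over an avoided crossing agrees with the
        deterministic product Π(1−g) of the same fewest-switches sequence."""
        n_frames, dt, J = 240, 0.5, 0.005
        t = np.arange(n_frames) * dt
        slope = 4e-4
        e1 = slope * (t - t[-1] / 2)
        traj = SiteHamiltonianTrajectory(
            times=t, site_energies=np.stack([e1, -e1], axis=1),
            couplings=np.broadcast_to(np.array([[0.0, J], [J, 0.0]]),
                                      (n_frames, 2, 2)).copy(),
            site_positions=np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        psi = propagate_wavefunction(traj, np.array([1, 0], complex), substeps=5)
        hams = [traj.hamiltonian(f) for f in range(n_frames)]
        eig = [_sorted_eigh(h) for h in hams]

        g_seq = []
        for f in range(n_frames - 1):
            psi_ad = eig[f][1].T @ psi[f]
            g = fewest_switches_probabilities(hams[f], hams[f + 1], psi_ad, 0, dt)
            g_seq.append(g[1])
        p_stay_exact = np.prod(1.0 - np.array(g_seq))

        rng_master = np.random.default_rng(42)
        n_runs = 1500
        stays = 0
        for _ in range(n_runs):
            rng = np.random.default_rng(int(rng_master.integers(2**31)))
            active = 0
            for f in range(n_frames - 1):
                active = surface_hop_step(hams[f], hams[f + 1], psi[f],
                                          active, dt, rng)
                if active != 0:
                    break
            stays += active == 0
        p_mc = stays / n_runs
        sigma = np.sqrt(p_stay_exact * (1 - p_stay_exact) / n_runs)
        assert abs(p_mc - p_stay_exact) < 3 * sigma


class TestObservables:
    def test_ipr_exact_values(self):
        n = 8
        localized = np.zeros((1, n), complex)
        localized[0, 0] = 1.0
        assert ipr(localized)[0] == pytest.approx(1.0)
        uniform = np.full((1, 4), 0.5, complex)
        assert ipr(uniform)[0] == pytest.approx(4.0)
        two = np.zeros((1, n), complex)
        two[0, :2] = 1 / np.sqrt(2)
        assert ipr(two)[0] == pytest.approx(2.0)

    def test_ipr_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            ipr(np.full((1, 4), 0.9, complex))

    def test_msd_single_site_values(self):
        pos = np.array([[0.0, 0, 0], [3.0, 4.0, 0.0]])
        psi = np.zeros((2, 2), complex)
        psi[0, 0] = 1.0   # start localized at origin
        psi[1, 1] = 1.0   # then fully transferred
        msd = msd_tensor(psi, pos)
        assert np.allclose(msd[0], 0.0)
        assert msd[1, 0, 0] == pytest.approx(9.0)
        assert msd[1, 1, 1] == pytest.approx(16.0)
        assert msd[1, 0, 1] == pytest.approx(12.0)
        assert np.allclose(msd[1], msd[1].T)

    def test_msd_symmetric_two_site_split(self):
        d = 4.0
        pos = np.array([[-d, 0, 0], [d, 0, 0]])
        psi = np.full((1, 2), 1 / np.sqrt(2), complex)
        msd = msd_tensor(psi, pos, origin=np.zeros(3))
        assert msd[0, 0, 0] == pytest.approx(d**2)

    def test_diffusion_from_linear_msd(self):
        t = np.linspace(0, 1000, 200)
        msd = np.zeros((200, 3, 3))
        msd[:, 0, 0] = 2.0 * 0.01 * t       # MSD = 2 a t with a = 0.01 Å²/fs
        d = diffusion_from_msd(t, msd)
        assert d[0, 0] == pytest.approx(0.01 * 1e-1, rel=1e-9)  # cm²/s
        assert d[1, 1] == 0.0

    def test_diffusion_noisy_slope(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 1000, 400)
        msd = np.zeros((400, 3, 3))
        msd[:, 0, 0] = 1e-3 * t + rng.normal(0, 0.05, 400)  # 1 Å²/ps slope
        d = diffusion_from_msd(t, msd)
        assert d[0, 0] == pytest.approx(5e-5, rel=0.05)

    def test_mobility_conversion(self):
        d = np.diag([1e-3, 0.0, 0.0])
        mu = mobility_from_diffusion(d, 300.0)
        assert mu[0, 0] == pytest.approx(1e-3 / 0.0258520, rel=1e-4)
        assert mu[1, 1] == 0.0
        assert mobility_from_diffusion(d, 600.0)[0, 0] == pytest.approx(
            mu[0, 0] / 2.0, rel=1e-9)

    def test_disorder_lowers_ipr_and_mobility(self):
        """Site-energy disorder localizes the carrier: lower IPR and mobility."""
        def chain(sigma):
            def factory(seed):
                return make_hamiltonian_chain(40, 0.02, sigma, 100.0, 1.0, 600,
                                              seed=seed)
            return transport_observables(factory(1), n_trajectories=4,
                                         substeps=5, trajectory_factory=factory)

        ordered = chain(0.0)
        disordered = chain(0.05)
        tail = slice(-100, None)
        assert disordered.ipr[tail].mean() < ordered.ipr[tail].mean()
        assert disordered.mobility[0, 0] < ordered.mobility[0, 0]

    def test_msd_positive_semidefinite(self):
        traj = make_hamiltonian_chain(20, 0.02, 0.03, 100.0, 1.0, 300, seed=9)
        psi0 = np.zeros(20, complex)
        psi0[10] = 1.0
        psi = propagate_wavefunction(traj, psi0)
        msd = msd_tensor(psi, traj.site_positions)
        for frame in range(0, 300, 50):
            eigvals = np.linalg.eigvalsh(msd[frame])
            assert eigvals.min() > -1e-10
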