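"""Reorganization-energy estimators, continuum theory and error metrics."""

import numpy as np
import pytest

from sitefield.core import InvalidParameterError
from sitefield.fixtures import make_gap_series
from sitefield.md import BondTerm
from sitefield.reorg import (ChargeStateBuilder, DielectricParams, GapSeries,
                             apply_charge_scaling, build_charged_state_bonds,
                             charge_scale_factor, error_metrics,
                             lambda_four_point, lambda_stokes, lambda_variance,
                             marcus_continuum, mobility_anisotropy,
                             pekar_ratio, split_inner_outer)
from sitefield.core import MoleculeChargeSpec
from sitefield.units import COULOMB_CONSTANT as KE
from sitefield.units import K_B


class TestGapEstimators:
    def test_constant_gaps(self):
        series = GapSeries(np.full(100, 0.2), 300.0)
        mean, err = lambda_stokes(series)
        assert mean == pytest.approx(0.2)
        assert err == pytest.approx(0.0, abs=1e-15)
        assert lambda_variance(series) == pytest.approx(0.0, abs=1e-15)

    def test_antisymmetric_series_zero_mean(self):
        series = GapSeries(np.concatenate([np.arange(10), -np.arange(10)]), 300.0)
        assert lambda_stokes(series)[0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_gaps_recover_generator_mean(self):
        series = make_gap_series(0.19, 300.0, 5000, seed=12)
        mean, err = lambda_stokes(series)
        assert mean == pytest.approx(0.19, abs=3 * 0.0992 / np.sqrt(5000))
        assert err > 0

    def test_variance_estimator_closed_form(self):
        rng = np.random.default_rng(3)
        gaps = rng.normal(0.0, 0.1, 20000)
        series = GapSeries(gaps, 300.0)
        expected = 0.1**2 / (2 * K_B * 300.0)
        assert lambda_variance(series) == pytest.approx(expected, rel=0.05)

    def test_variance_quadratic_scaling(self):
        rng = np.random.default_rng(4)
        gaps = rng.normal(0.0, 0.05, 4000)
        s1 = GapSeries(gaps, 300.0)
        s2 = GapSeries(2 * gaps, 300.0)
        assert lambda_variance(s2) == pytest.approx(4 * lambda_variance(s1),
                                                    rel=1e-12)

    def test_linear_response_consistency(self):
        """Generated under linear response, λ^st ≈ λ^var within 5 %."""
        series = make_gap_series(0.19, 300.0, 5000, seed=7)
        st, _ = lambda_stokes(series)
        var = lambda_variance(series)
        assert abs(st - var) / st < 0.05

    def test_temperature_validation(self):
        with pytest.raises(InvalidParameterError):
            GapSeries(np.ones(5), -1.0)


class TestFourPoint:
    def test_arithmetic(self):
        assert lambda_four_point(0.0, 1.0, 1.0, 0.0) == pytest.approx(2.0)
        assert lambda_four_point(1.0, 1.0, 1.0, 1.0) == 0.0

    def test_harmonic_dimer_closed_form(self):
        # two 1-D harmonic molecules, minima displaced by d between states:
        # E_A(x1,x2) = ½k(x1−d)² + ½k x2², E_B = ½k x1² + ½k(x2−d)²
        k, d = 10.0, 0.05
        e_a = lambda x1, x2: 0.5 * k * (x1 - d) ** 2 + 0.5 * k * x2**2
        e_b = lambda x1, x2: 0.5 * k * x1**2 + 0.5 * k * (x2 - d) ** 2
        # R_A = (d, 0) minimizes E_A, R_B = (0, d) minimizes E_B
        lam = lambda_four_point(e_a(d, 0), e_b(d, 0), e_a(0, d), e_b(0, d))
        # each end state is displaced by d on both molecules: λ = 2·k·d²
        assert lam == pytest.approx(2 * k * d**2)
        assert lam == pytest.approx(0.05)

    def test_split_inner_outer(self):
        assert split_inner_outer(0.219, 0.142) == pytest.approx(0.077)
        assert split_inner_outer(0.190, 0.142) == pytest.approx(0.048)
        assert split_inner_outer(0.142, 0.142) == 0.0


class TestContinuum:
    def test_marcus_zero_for_equal_dielectrics(self):
        p = DielectricParams(3.0, 3.0, 2.0, 2.0, 8.0)
        assert marcus_continuum(p) == 0.0

    def test_marcus_scalar_oracle(self):
        p = DielectricParams(2.0, 4.0, 2.0, 2.0, 8.0)
        assert marcus_continuum(p) == pytest.approx(0.25 * 0.375 * KE, rel=1e-12)

    def test_marcus_infinite_distance_limit(self):
        near = marcus_continuum(DielectricParams(2.0, 4.0, 2.0, 2.0, 1e9))
        assert near == pytest.approx(0.25 * 0.5 * KE, rel=1e-6)

    def test_pekar_ratio_printed_dielectrics(self):
        assert round(pekar_ratio(2.6, 3.2), 1) == 9.5

    def test_pekar_ratio_limits(self):
        assert pekar_ratio(1.0, 3.2) == pytest.approx(1.0)
        assert pekar_ratio(2.0, 4.0) == pytest.approx(3.0)
        with pytest.raises(InvalidParameterError):
            pekar_ratio(3.0, 3.0)

    def test_pekar_monotone_in_eps_op(self):
        vals = [pekar_ratio(e, 4.0) for e in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_charge_scale_factor(self):
        assert round(charge_scale_factor(2.6), 2) == 0.62
        assert charge_scale_factor(1.0) == 1.0
        assert charge_scale_factor(4.0) == 0.5
        vals = [charge_scale_factor(e) for e in (1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestChargeStateBuilder:
    def spec(self):
        return MoleculeChargeSpec([-0.3, 0.14, 0.10, 0.06],
                                  [0.1, 0.34, 0.30, 0.26], 1.0)

    def test_gamma_one_is_identity(self):
        spec = self.spec()
        builder = ChargeStateBuilder(delta_charges=[0.4, 0.2, 0.2, 0.2],
                                     gamma=1.0)
        out = apply_charge_scaling(spec, builder)
        assert np.allclose(out.neutral_charges, spec.neutral_charges)
        assert np.allclose(out.charged_charges, spec.charged_charges)

    def test_net_charge_preserved_for_any_gamma(self):
        spec = self.spec()
        for gamma in (0.62, 0.80, 1.2):
            out = apply_charge_scaling(
                spec, ChargeStateBuilder([0.4, 0.2, 0.2, 0.2], gamma=gamma))
            assert out.charged_charges.sum() == pytest.approx(1.0, abs=1e-12)
            assert out.neutral_charges.sum() == pytest.approx(0.0, abs=1e-12)

    def test_elementwise_hand_computation(self):
        out = apply_charge_scaling(
            self.spec(), ChargeStateBuilder([0.4, 0.2, 0.2, 0.2], gamma=0.80))
        assert np.allclose(out.neutral_charges, [-0.24, 0.112, 0.08, 0.048])
        assert np.allclose(out.charged_charges, [0.16, 0.312, 0.28, 0.248])

    def test_inconsistent_delta_rejected(self):
        with pytest.raises(InvalidParameterError):
            apply_charge_scaling(
                self.spec(), ChargeStateBuilder([0.1, 0.1, 0.1, 0.1]))

    def test_charged_bond_lengths(self):
        bonds = [BondTerm(0, 1, 10.0, 1.10, 1.10),
                 BondTerm(0, 2, 10.0, 1.10, 1.10)]
        builder = ChargeStateBuilder([1.0], delta_bonds=[0.05, 0.02], beta=0.88)
        out = build_charged_state_bonds(bonds, builder)
        assert out[0].r0_charged == pytest.approx(1.10 + 0.88 * 0.05)
        assert out[1].r0_charged == pytest.approx(1.10 + 0.88 * 0.02)
        zero = build_charged_state_bonds(
            bonds, ChargeStateBuilder([1.0], delta_bonds=[0.05, 0.02], beta=1e-9))
        assert zero[0].r0_charged == pytest.approx(1.10, abs=1e-9)
        with pytest.raises(InvalidParameterError):
            build_charged_state_bonds(bonds, ChargeStateBuilder([1.0],
                                                                delta_bonds=[0.05]))


class TestErrorMetrics:
    def test_identical_series(self):
        metrics = error_metrics(np.array([0.0, 2.0]), np.array([0.0, 2.0]))
        assert metrics["mue_over_muf_percent"] == 0.0
        assert metrics["max_over_muf_percent"] == 0.0

    def test_worked_example(self):
        metrics = error_metrics(np.array([0.0, 2.0]), np.array([0.0, 3.0]))
        assert metrics["muf"] == pytest.approx(1.0)
        assert metrics["mue"] == pytest.approx(0.5)
        assert metrics["mue_over_muf_percent"] == pytest.approx(50.0)

    def test_centering_removes_constant_offset(self):
        ref = np.array([1.0, 2.0, 3.0, 2.0])
        metrics = error_metrics(ref, ref + 5.0)
        assert metrics["mue_over_muf_percent"] == pytest.approx(0.0, abs=1e-10)
        raw = error_metrics(ref, ref + 5.0, center=False)
        assert raw["mue"] == pytest.approx(5.0)

    def test_zero_fluctuation_rejected(self):
        with pytest.raises(InvalidParameterError):
            error_metrics(np.ones(4), np.zeros(4))


def test_mobility_anisotropy():
    assert round(mobility_anisotropy(3.2, 1.4), 1) == 2.3
    assert round(mobility_anisotropy(3.5, 2.0), 1) == 1.8
    assert mobility_anisotropy(2.0, 2.0) == 1.0
    with pytest.raises(InvalidParameterError):
        mobility_anisotropy(1.0, 0.0)
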