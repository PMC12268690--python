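"""Closed-form thermodynamics: supersaturation, van 't Hoff, kink density."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stepkin.constants import R_GAS
from stepkin.errors import DomainError, InsufficientDataError
from stepkin.thermo import (
    NucleationInputs,
    SolubilityPoint,
    equilibrium_kink_density,
    face_growth_rate,
    fit_vant_hoff,
    gibbs_from_hs,
    gibbs_from_solubility,
    kelvin,
    nucleation_barrier_2d,
    restricted_sos_kink_density_enumeration,
    solubility_from_thermo,
    supersaturation,
)

positive_conc = st.floats(min_value=1e-6, max_value=10.0)


@pytest.mark.parametrize(
    "c, ce, expected",
    [
        (0.0135, 0.0135, 0.0),
        (0.0167, 0.0135, math.log(16.7 / 13.5)),
        (0.00675, 0.0135, math.log(0.5)),
    ],
)
def test_supersaturation_values(c, ce, expected):
    assert supersaturation(c, ce) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(positive_conc, positive_conc)
def test_supersaturation_antisymmetry(c, ce):
    assert supersaturation(c, ce) + supersaturation(ce, c) == pytest.approx(0.0, abs=1e-9)


def test_supersaturation_names_offending_argument():
    with pytest.raises(DomainError, match="concentration"):
        supersaturation(-1.0, 0.0135)
    with pytest.raises(DomainError, match="equilibrium_concentration"):
        supersaturation(0.0135, 0.0)


def test_kelvin_requires_explicit_unit():
    assert kelvin(25.0, "C") == pytest.approx(298.15)
    assert kelvin(298.15, "K") == 298.15
    with pytest.raises(DomainError):
        kelvin(25.0, "F")


class TestVantHoff:
    def test_noiseless_recovery_to_machine_precision(self):
        dh, ds = -20.5e3, -34.0
        pts = [
            SolubilityPoint(t, solubility_from_thermo(dh, ds, t))
            for t in (283.0, 288.0, 293.0, 300.0)
        ]
        fit = fit_vant_hoff(pts)
        assert fit.enthalpy == pytest.approx(dh, rel=1e-10)
        assert fit.entropy == pytest.approx(ds, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_exact_line_zero_residual(self):
        dh, ds = -18e3, -30.0
        pts = [SolubilityPoint(t, solubility_from_thermo(dh, ds, t)) for t in (280.0, 300.0)]
        fit = fit_vant_hoff(pts)
        assert fit.enthalpy == pytest.approx(dh, rel=1e-12)
        assert max(abs(r) for r in fit.residuals) < 1e-12
        assert fit.enthalpy_se == 0.0

    def test_insufficient_distinct_temperatures(self):
        pts = [SolubilityPoint(290.0, 0.01), SolubilityPoint(290.0, 0.012)]
        with pytest.raises(InsufficientDataError):
            fit_vant_hoff(pts)

    def test_weighted_fit_needs_uncertainties(self):
        pts = [SolubilityPoint(t, 0.01 * (1 + 0.01 * i)) for i, t in enumerate((280.0, 290.0, 300.0))]
        with pytest.raises(InsufficientDataError):
            fit_vant_hoff(pts, weighted=True)

    def test_weighted_fit_runs_with_uncertainties(self):
        dh, ds = -20.5e3, -34.0
        pts = [
            SolubilityPoint(t, solubility_from_thermo(dh, ds, t), uncertainty=1e-4)
            for t in (283.0, 290.0, 300.0)
        ]
        fit = fit_vant_hoff(pts, weighted=True)
        assert fit.enthalpy == pytest.approx(dh, rel=1e-9)


class TestGibbs:
    def test_one_molar_reference_is_zero(self):
        assert gibbs_from_solubility(1.0, 310.0) == 0.0

    def test_theophylline_solubility_gives_reported_gibbs(self):
        # 13.5 mM at 25.2 C lands within the +-0.7 kJ/mol of -10.5
        g = gibbs_from_solubility(0.0135, 298.35)
        assert g == pytest.approx(-10.68e3, abs=20.0)
        assert abs(g - (-10.5e3)) < 0.7e3

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=-40e3, max_value=-5e3),
        st.floats(min_value=-60.0, max_value=-5.0),
        st.floats(min_value=270.0, max_value=330.0),
    )
    def test_solubility_gibbs_inverse_pair(self, dh, ds, t):
        ce = solubility_from_thermo(dh, ds, t)
        assert gibbs_from_solubility(ce, t) == pytest.approx(gibbs_from_hs(dh, ds, t), rel=1e-12)

    def test_gibbs_from_hs_degenerate_cases(self):
        assert gibbs_from_hs(-5e3, 0.0, 298.0) == -5e3
        assert gibbs_from_hs(0.0, -34.0, 298.0) == 298.0 * 34.0

    def test_triplet_matches_reported_gibbs_within_error_bar(self):
        assert gibbs_from_hs(-20.5e3, -34.0, 298.0) == pytest.approx(-10.37e3, abs=10.0)
        assert abs(gibbs_from_hs(-20.5e3, -34.0, 298.0) - (-10.5e3)) < 0.7e3

    def test_solubility_from_thermo_scale(self):
        # the rounded enthalpy/entropy pair implies ~15.4 mM, same order as
        # the measured 13.5 mM (documented rounding discrepancy, not asserted equal)
        assert solubility_from_thermo(-20.5e3, -34.0, 298.35) == pytest.approx(0.0154, abs=2e-4)

    def test_zero_gibbs_means_one_molar(self):
        assert solubility_from_thermo(-30e3, -30e3 / 298.0, 298.0) == pytest.approx(1.0, rel=1e-9)

    def test_overflow_guard(self):
        with pytest.raises(DomainError, match="overflow"):
            solubility_from_thermo(1e6, 0.0, 200.0)


class TestKinkDensity:
    def test_zero_energy_limit(self):
        assert equilibrium_kink_density(0.0, 298.0) == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_reported_kink_energy_value(self):
        assert equilibrium_kink_density(4e3, 298.15) == pytest.approx(0.2849, abs=5e-4)

    def test_kink_poor_step(self):
        val = equilibrium_kink_density(40e3, 298.0)
        assert val == pytest.approx(2.0 / (math.exp(40e3 / (R_GAS * 298.0)) + 2.0), rel=1e-12)
        assert val < 1e-6

    def test_negative_energy_rejected(self):
        with pytest.raises(DomainError):
            equilibrium_kink_density(-1.0, 298.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.0, max_value=50e3), st.floats(min_value=250.0, max_value=350.0))
    def test_matches_three_state_enumeration_and_bounds(self, omega, t):
        val = equilibrium_kink_density(omega, t)
        assert 0.0 < val <= 2.0 / 3.0
        assert val == pytest.approx(restricted_sos_kink_density_enumeration(omega, t), rel=1e-12)

    def test_strictly_decreasing_in_kink_energy(self):
        omegas = np.linspace(0.0, 30e3, 50)
        vals = [equilibrium_kink_density(w, 298.0) for w in omegas]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestNucleationBarrier:
    def _inputs(self, gamma=1e-11, dmu=500.0):
        return NucleationInputs(
            molecular_volume=193.4, layer_thickness=0.84743, edge_free_energy=gamma, driving_force=dmu
        )

    def test_inverse_proportionality_in_driving_force(self):
        b1 = nucleation_barrier_2d(self._inputs(dmu=400.0))
        b2 = nucleation_barrier_2d(self._inputs(dmu=800.0))
        assert b1 == pytest.approx(2.0 * b2, rel=1e-12)

    def test_square_law_in_edge_energy(self):
        b1 = nucleation_barrier_2d(self._inputs(gamma=1e-11))
        b2 = nucleation_barrier_2d(self._inputs(gamma=2e-11))
        assert b2 == pytest.approx(4.0 * b1, rel=1e-12)

    def test_unit_tracked_evaluation(self):
        # manual evaluation: pi * (193.4e-30 m^3) * (1e-11 J/m)^2
        #                    / (0.84743e-9 m * 500/N_A J)
        from stepkin.constants import N_AVOGADRO

        expected = math.pi * 193.4e-30 * 1e-22 / (0.84743e-9 * 500.0 / N_AVOGADRO)
        assert nucleation_barrier_2d(self._inputs()) == pytest.approx(expected, rel=1e-12)
        assert nucleation_barrier_2d(self._inputs()) > 0

    def test_nonpositive_driving_force_rejected(self):
        with pytest.raises(DomainError):
            self._inputs(dmu=0.0)


class TestFaceGrowthRate:
    def test_arithmetic(self):
        assert face_growth_rate(2.413, 1.0, 241.3) == pytest.approx(0.01, rel=1e-12)

    def test_halving_spacing_doubles_rate(self):
        assert face_growth_rate(2.413, 0.7, 100.0) == pytest.approx(
            0.5 * face_growth_rate(2.413, 0.7, 50.0), rel=1e-12
        )

    def test_direct_multiplication_oracle(self):
        h, v, l = 2.413, 0.42, 173.0
        assert face_growth_rate(h, v, l) == h * v / l

    def test_zero_spacing_rejected(self):
        with pytest.raises(DomainError):
            face_growth_rate(2.413, 1.0, 0.0)
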