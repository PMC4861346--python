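"""Constraint equations, flux laws and the membrane-potential solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pumpleak as pl
from pumpleak.model import _voltage_factor

MEDIUM = pl.Medium(na0=140, k0=5.8, l0=5, cl0=121, B0=48.2)   # S_o = 320

# the balanced state of the reference system, as printed
BAL = dict(na=38.6, k=155.2, l=4.375, cl=72.1)
U_BAL = -47.5


def cell_at(na, k, l, cl, medium=MEDIUM):
    return pl.CellState.from_concentrations(na, k, l, cl, medium)


@pytest.fixture(scope="module")
def params():
    return pl.TransportParams(beta=0.039, gamma=1.5, pna=0.00349,
                              pk=0.0229, pl=0.00349, pcl=0.00426,
                              inc=3e-5, ilc=0.00018, kp=0.0002)


class TestConstraintEquations:
    def test_valence_reference_state(self):
        # kv-adjusted initial state of the reference system
        z = pl.compute_impermeant_valence(
            (38.184, 163.056, 0.0001032, 65.016), MEDIUM)
        assert z == pytest.approx(-2.53, abs=0.005)

    def test_valence_zero_charge(self):
        # cl = na + k + l leaves no deficit for the impermeant anion
        z = pl.compute_impermeant_valence((50, 60, 10, 120),
                                          pl.Medium(100, 50, 10, 120, 20))
        assert z == 0.0

    def test_valence_hand_arithmetic(self):
        med = pl.Medium(na0=150, k0=50, l0=0, cl0=80, B0=20)  # S_o = 300
        z = pl.compute_impermeant_valence((50, 100, 0, 50), med)
        assert z == pytest.approx(-1.0, rel=1e-12)

    def test_valence_reproduces_charge_deficit(self):
        cell = cell_at(38.184, 163.056, 0.0001032, 65.016)
        deficit = cell.cl - cell.na - cell.k - cell.l
        assert cell.z * (cell.A / cell.V) == pytest.approx(deficit, rel=1e-12)

    def test_water_per_impermeant(self):
        va = pl.compute_water_per_impermeant(
            (38.184, 163.056, 0.0001032, 65.016), MEDIUM)
        assert va * 1000 == pytest.approx(18.61, abs=0.005)
        va_bal = pl.compute_water_per_impermeant(
            (BAL["na"], BAL["k"], BAL["l"], BAL["cl"]), MEDIUM)
        assert va_bal * 1000 == pytest.approx(20.10, abs=0.02)

    def test_water_trivial_arithmetic(self):
        med = pl.Medium(na0=150, k0=50, l0=0, cl0=80, B0=20)
        va = pl.compute_water_per_impermeant((100, 100, 0, 50), med)
        assert va == pytest.approx(0.02, rel=1e-12)
        assert 1 / va == pytest.approx(50, rel=1e-12)

    def test_overfull_cell_is_bad_initial_data(self):
        with pytest.raises(pl.BadInitialData, match="BAD INITIAL DATA"):
            pl.compute_impermeant_valence((200, 100, 10, 50), MEDIUM)

    def test_state_satisfies_both_constraints(self):
        cell = cell_at(38.184, 163.056, 0.0001032, 65.016)
        assert cell.charge_content == pytest.approx(0.0, abs=1e-12)
        osm = cell.na + cell.k + cell.l + cell.cl + cell.A / cell.V
        assert osm == pytest.approx(MEDIUM.osmolarity, rel=1e-14)


class TestCotransport:
    def test_nc_and_ln_reference_values(self, params):
        cell = cell_at(BAL["na"], BAL["k"], BAL["l"], BAL["cl"])
        j = pl.cotransport_fluxes(cell, MEDIUM, params)
        assert j.JNC == pytest.approx(0.4248, abs=1e-4)
        assert j.JLN == pytest.approx(0.0839, abs=1e-4)
        assert j.JLC == pytest.approx(0.0521, abs=1e-4)

    def test_equilibrium_product_gives_zero(self, params):
        # inside products equal outside products for every carrier
        med = pl.Medium(na0=100, k0=100, l0=100, cl0=100, B0=100)
        cell = cell_at(100, 100, 100, 100, med)
        j = pl.cotransport_fluxes(cell, med, params)
        assert all(v == 0.0 for v in j)

    @given(scale=st.floats(0.2, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_ln_sign_follows_product_difference(self, params, scale):
        # JLN > 0 iff [Na]o[Li]i > [Na]i[Li]o
        cell = cell_at(40, 150, 4 * scale, 70)
        j = pl.cotransport_fluxes(cell, MEDIUM, params)
        drive = MEDIUM.na0 * cell.l - cell.na * MEDIUM.l0
        assert math.copysign(1, j.JLN) == math.copysign(1, drive) or j.JLN == 0


class TestChannelFlux:
    def test_reference_net_fluxes(self, params):
        cell = cell_at(BAL["na"], BAL["k"], BAL["l"], BAL["cl"])
        u = U_BAL / pl.RTF
        assert pl.channel_net_flux("na", cell, MEDIUM, params, u) == \
            pytest.approx(0.9975, abs=1e-3)
        assert pl.channel_net_flux("k", cell, MEDIUM, params, u) == \
            pytest.approx(-0.9989, abs=1e-3)
        assert pl.channel_net_flux("cl", cell, MEDIUM, params, u) == \
            pytest.approx(-0.4712, abs=1e-3)

    def test_small_voltage_limit(self, params):
        # u -> 0: cation flux -> p*(c_o - c_i); anion flux mirrored
        cell = cell_at(38, 155, 4, 72)
        for u in (1e-8, -1e-8):
            fna = pl.channel_net_flux("na", cell, MEDIUM, params, u)
            assert fna == pytest.approx(
                params.pna * (MEDIUM.na0 - cell.na), rel=1e-6)
            fcl = pl.channel_net_flux("cl", cell, MEDIUM, params, u)
            assert fcl == pytest.approx(
                params.pcl * (MEDIUM.cl0 - cell.cl), rel=1e-6)

    def test_voltage_factor_continuity(self):
        # series branch meets the closed form to 6 significant figures
        for u in (1e-8, -1e-8, 9e-7, -9e-7):
            exact = u / (1 - math.exp(u))
            assert _voltage_factor(u) == pytest.approx(exact, rel=1e-6)

    def test_nernst_equilibrium_null(self, params):
        # state built directly: only the flux law is under test here
        u = -1.2
        cell = pl.CellState(na=140 * math.exp(-u), k=100, l=1,
                            cl=121 * math.exp(u), V=0.02, z=0.0)
        assert pl.channel_net_flux("na", cell, MEDIUM, params, u) == \
            pytest.approx(0.0, abs=1e-12)
        assert pl.channel_net_flux("cl", cell, MEDIUM, params, u) == \
            pytest.approx(0.0, abs=1e-12)

    def test_unknown_ion_rejected(self, params):
        cell = cell_at(38, 155, 4, 72)
        with pytest.raises(ValueError, match="unknown ion"):
            pl.channel_net_flux("rb", cell, MEDIUM, params, -1.0)


class TestPumpFluxes:
    @pytest.mark.parametrize("beta,na,expected_eff,expected_kin", [
        (0.039, 38.6, -1.5051, 1.0034),
        (0.039, 37.0, -1.443, 0.962),
        (0.0, 38.6, 0.0, 0.0),
    ])
    def test_sodium_pump(self, beta, na, expected_eff, expected_kin):
        cell = cell_at(na, 155, 4, 72)
        p = pl.TransportParams(beta=beta, gamma=1.5, pna=1e-3)
        flux = pl.pump_fluxes(cell, p)
        assert flux.na_efflux == pytest.approx(expected_eff, abs=5e-4)
        assert flux.k_influx == pytest.approx(expected_kin, abs=5e-4)

    def test_lithium_pump_mode(self):
        cell = cell_at(38, 155, 10, 72)
        p = pl.TransportParams(alpha=0.004, gamma=1.5, pna=1e-3)
        flux = pl.pump_fluxes(cell, p)
        assert flux.li_efflux == pytest.approx(-0.04, rel=1e-12)
        assert flux.k_influx == pytest.approx(0.04 / 1.5, rel=1e-12)


class TestMembranePotential:
    def test_initial_state_potential(self, params):
        cell = cell_at(38.184, 163.056, 0.0001032, 65.016)
        pot = pl.solve_membrane_potential(cell, MEDIUM, params)
        assert pot.U == pytest.approx(-49.4, abs=0.05)
        assert pot.U == pytest.approx(pot.u * 26.7, rel=1e-14)

    def test_balanced_state_potential(self, params, balanced_cell, reference_run):
        pot = pl.solve_membrane_potential(balanced_cell, reference_run.medium,
                                          reference_run.params)
        assert pot.U == pytest.approx(-47.5, abs=0.05)

    def test_residual_below_tolerance(self, params):
        cell = cell_at(38.184, 163.056, 0.0001032, 65.016)
        pot = pl.solve_membrane_potential(cell, MEDIUM, params)
        assert abs(pl.total_charge_flux(cell, MEDIUM, params, pot.u)) < 1e-10

    def test_no_gradients_no_pump_gives_zero(self):
        med = pl.Medium(na0=100, k0=100, l0=100, cl0=100, B0=100)
        cell = cell_at(100, 100, 100, 100, med)
        p = pl.TransportParams(pna=0.003, pk=0.02, pl=0.003, pcl=0.004)
        pot = pl.solve_membrane_potential(cell, med, p)
        assert pot.U == pytest.approx(0.0, abs=1e-9)

    def test_range_limit_without_permeabilities(self):
        cell = cell_at(38, 155, 4, 72)
        p = pl.TransportParams(beta=0.039)    # charge flux never crosses 0
        with pytest.raises(pl.RangeLimit, match="RANGE LIMIT"):
            pl.solve_membrane_potential(cell, MEDIUM, p)

    def test_warm_start_matches_cold_start(self, params):
        cell = cell_at(38.184, 163.056, 0.0001032, 65.016)
        cold = pl.solve_membrane_potential(cell, MEDIUM, params)
        warm = pl.solve_membrane_potential(cell, MEDIUM, params,
                                           u_hint=cold.u + 0.01)
        assert warm.u == pytest.approx(cold.u, abs=1e-11)

    def test_root_unique_on_fixture_states(self, params, balanced_cell,
                                           reference_run):
        # 400-point sign scan over the search window: exactly one crossing
        for cell, medium, prm in [
            (cell_at(38.184, 163.056, 0.0001032, 65.016), MEDIUM, params),
            (balanced_cell, reference_run.medium, reference_run.params),
        ]:
            us = np.linspace(pl.U_MIN / pl.RTF, pl.U_MAX / pl.RTF, 400)
            vals = np.array([pl.total_charge_flux(cell, medium, prm, u)
                             for u in us])
            crossings = np.sum(np.sign(vals[:-1]) != np.sign(vals[1:]))
            assert crossings == 1


class TestElectrochemicalPotentials:
    def test_balanced_state_values(self):
        cell = cell_at(BAL["na"], BAL["k"], BAL["l"], BAL["cl"])
        mu = pl.electrochemical_potentials(cell, MEDIUM, U_BAL)
        assert mu.mun == pytest.approx(-81.9, abs=0.1)
        assert mu.mucl == pytest.approx(33.7, abs=0.1)

    def test_chloride_hand_value(self):
        cell = cell_at(38.6, 155.2, 4.375, 72.1)
        mu = pl.electrochemical_potentials(cell, MEDIUM, -47.5)
        assert mu.mucl == pytest.approx(26.7 * math.log(72.1 / 121) + 47.5,
                                        rel=1e-12)
        assert mu.mucl == pytest.approx(33.68, abs=0.01)

    def test_equal_concentration_zero_potential(self):
        med = pl.Medium(na0=38.6, k0=160, l0=5, cl0=80, B0=60)
        cell = cell_at(38.6, 155, 4, 72, med)
        mu = pl.electrochemical_potentials(cell, med, 0.0)
        assert mu.mun == pytest.approx(0.0, abs=1e-12)

    def test_zero_concentration_sentinel(self):
        cell = pl.CellState(na=38, k=155, l=0.0, cl=72, V=0.02, z=-2.5)
        mu = pl.electrochemical_potentials(cell, MEDIUM, -49.4)
        assert mu.mul == -math.inf

    def test_trace_lithium_is_large_negative(self):
        # the stored trace concentration is used as-is, nothing clamped
        cell = pl.CellState(na=38.184, k=163.056, l=0.0001032, cl=65.016,
                            V=0.0186, z=-2.53)
        mu = pl.electrochemical_potentials(cell, MEDIUM, -49.4)
        assert -345 < mu.mul < -330


class TestContentDerivatives:
    def test_balanced_state_is_stationary(self, converged_run):
        cell = converged_run.cell
        d = pl.content_derivatives(cell, converged_run.medium,
                                   converged_run.params,
                                   converged_run.potential.u)
        assert max(abs(v) for v in d) < 1e-3 * cell.V

    def test_pump_only_system(self):
        cell = cell_at(38, 155, 4, 72)
        p = pl.TransportParams(beta=0.04, gamma=1.5)
        d = pl.content_derivatives(cell, MEDIUM, p, -1.0)
        assert d.na == pytest.approx(-0.04 * 38 * cell.V, rel=1e-12)
        assert d.l == 0.0

    def test_initial_state_flux_directions(self, params):
        # from the adjusted start: K leaves, Li and Cl load (per the
        # recorded time course: k 163.1 -> 155.2, l 0 -> 4.375)
        cell = cell_at(38.184, 163.056, 0.0001032, 65.016)
        pot = pl.solve_membrane_potential(cell, MEDIUM, params)
        d = pl.content_derivatives(cell, MEDIUM, params, pot.u)
        assert d.k < 0
        assert d.l > 0
        assert d.cl > 0
        # Na is nearly stationary from the outset (38.2 -> 38.0 -> 38.6)
        assert abs(d.na) < 0.5 * abs(d.l)

    def test_charge_flux_closure(self, params, balanced_cell, reference_run):
        # the signed derivative sum vanishes at the solved potential
        for cell, medium, prm in [
            (cell_at(38.184, 163.056, 0.0001032, 65.016), MEDIUM, params),
            (balanced_cell, reference_run.medium, reference_run.params),
        ]:
            pot = pl.solve_membrane_potential(cell, medium, prm)
            d = pl.content_derivatives(cell, medium, prm, pot.u)
            signed = d.na + d.k + d.l - d.cl
            scale = max(abs(v) for v in d) or 1.0
            assert abs(signed) < 1e-9 * scale


class TestTypeValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            pl.Medium(na0=-1, k0=5, l0=0, cl0=100, B0=40)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError, match="gamma"):
            pl.TransportParams(beta=0.04, gamma=1.0)

    def test_negative_rate_coefficient_rejected(self):
        with pytest.raises(ValueError, match="pna"):
            pl.TransportParams(pna=-0.001)
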