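"""Carrier-chain glucose transport: flux law, steady states, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from neuroglyc import transport as tr

CONC = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


def _linear_solve_flux(g_cis, g_trans, carrier):
    """Independent oracle: solve the 4x4 carrier-state balance directly."""
    k = carrier.kinetics
    a = k.kon * g_cis * 1e-3
    b = k.kon * g_trans * 1e-3
    d, f1, f2 = k.koff, k.f1, k.f2
    A = np.array([
        [-(f1 + a), d, f1, 0.0],
        [a, -(d + f2), 0.0, f2],
        [f1, 0.0, -(f1 + b), d],
        [1.0, 1.0, 1.0, 1.0],
    ])
    s = np.linalg.solve(A, [0.0, 0.0, 0.0, carrier.total_concentration])
    return f2 * (s[1] - s[3])


class TestCarrierFlux:
    def test_matches_linear_system_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            kin = tr.CarrierKinetics(
                f1=rng.uniform(10, 1000), f2=rng.uniform(100, 5000),
                kon=10 ** rng.uniform(6, 9), koff=10 ** rng.uniform(4, 7))
            carrier = tr.MembraneCarrier(rng.uniform(0.1, 5.0), kin)
            g1, g2 = rng.uniform(0, 30, size=2)
            assert tr.carrier_flux(g1, g2, carrier) == pytest.approx(
                _linear_solve_flux(g1, g2, carrier), rel=1e-10, abs=1e-12)

    @given(g=CONC)
    @settings(deadline=None)
    def test_zero_at_equal_concentrations(self, g):
        carrier = tr.MembraneCarrier(2.0)
        assert tr.carrier_flux(g, g, carrier) == 0.0

    @given(a=CONC, b=CONC)
    @settings(deadline=None)
    def test_antisymmetry(self, a, b):
        carrier = tr.MembraneCarrier(2.0)
        fwd = tr.carrier_flux(a, b, carrier)
        rev = tr.carrier_flux(b, a, carrier)
        assert fwd == pytest.approx(-rev, rel=1e-12, abs=1e-15)

    @given(a=CONC, b=CONC, factor=st.floats(min_value=0.1, max_value=10))
    @settings(deadline=None)
    def test_linear_in_carrier_amount(self, a, b, factor):
        c1 = tr.MembraneCarrier(1.0)
        c2 = tr.MembraneCarrier(factor)
        assert tr.carrier_flux(a, b, c2) == pytest.approx(
            factor * tr.carrier_flux(a, b, c1), rel=1e-12, abs=1e-15)

    def test_against_ode_relaxation_oracle(self):
        """The published rate set, 5.5 mM cis vs empty trans, vs the
        long-time limit of the four carrier-state ODEs."""
        carrier = tr.MembraneCarrier(2.0, tr.DEFAULT_CARRIER_KINETICS)
        g_cis, g_trans = 5.5, 0.0
        k = carrier.kinetics
        a, b, d = k.kon * g_cis * 1e-3, k.kon * g_trans * 1e-3, k.koff

        def rhs(_t, y):
            u1, b1, u2, b2 = y
            return [-(k.f1 + a) * u1 + d * b1 + k.f1 * u2,
                    a * u1 - (d + k.f2) * b1 + k.f2 * b2,
                    k.f1 * u1 - (k.f1 + b) * u2 + d * b2,
                    b * u2 - (d + k.f2) * b2 + k.f2 * b1]

        y0 = np.full(4, carrier.total_concentration / 4)
        sol = solve_ivp(rhs, (0, 1.0), y0, method="LSODA",
                        rtol=1e-12, atol=1e-14)
        flux_ode = k.f2 * (sol.y[1, -1] - sol.y[3, -1])
        assert tr.carrier_flux(g_cis, g_trans, carrier) == pytest.approx(
            flux_ode, rel=1e-3)

    def test_inverse_round_trip_and_saturation(self):
        carrier = tr.MembraneCarrier(2.0)
        flux = tr.carrier_flux(8.0, 1.0, carrier)
        assert tr.inverse_carrier_flux(flux, 1.0, carrier) == pytest.approx(8.0, rel=1e-10)
        with pytest.raises(tr.ConvergenceError):
            tr.inverse_carrier_flux(tr.carrier_flux_max(1.0, carrier) * 1.01,
                                    1.0, carrier)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            tr.carrier_flux(-1.0, 0.0, tr.MembraneCarrier(2.0))


class TestSteadyState:
    def test_gray_matter_euglycemia(self, gray_steady):
        """Published gray-matter parameters settle at G_in ~ 1.2 mM,
        F_hex ~ 6.5 uM/s at the euglycemic clamp level."""
        assert gray_steady.converged
        assert gray_steady.g_in == pytest.approx(1.2, abs=0.05)
        assert gray_steady.fhex == pytest.approx(6.5, abs=0.05)

    def test_flux_conservation_and_ordering(self, gray, gray_steady):
        res = gray_steady
        for f in res.carrier_fluxes:
            assert abs(f - res.fhex) < 1e-6
        gb = tr.EUGLYCEMIA.blood_glucose
        assert 0 < res.g_in < res.g_inter < res.g_endo < gb

    def test_zero_vmax_equilibrates_at_blood_glucose(self, gray):
        from dataclasses import replace

        tissue = replace(gray, hexokinase=tr.HexokinaseKinetics(0.0, 0.05))
        res = tr.solve_steady_state(tissue, tr.GlycemiaScenario(7.0))
        assert res.concentrations == pytest.approx((7.0, 7.0, 7.0))
        assert res.fhex == 0.0

    def test_matches_transient_ode_oracle_randomized(self):
        """Algebraic steady state vs terminal transient state, randomized
        tissues (seeded)."""
        rng = np.random.default_rng(42)
        for _ in range(8):
            scale = rng.uniform(0.3, 3.0)
            tissue = tr.gray_matter().scale_carriers(scale)
            from dataclasses import replace

            tissue = replace(tissue, hexokinase=tr.HexokinaseKinetics(
                vmax=rng.uniform(1.0, 8.0), km=rng.uniform(0.02, 1.0)))
            scenario = tr.GlycemiaScenario(rng.uniform(3.0, 20.0))
            res = tr.solve_steady_state(tissue, scenario)
            tra = tr.simulate_transient(tissue, scenario, duration=10000.0)
            assert tra.terminal[2] == pytest.approx(res.g_in, rel=5e-3)
            assert tra.fhex[-1] == pytest.approx(res.fhex, rel=5e-3)

    def test_fhex_monotone_in_blood_glucose_and_capped(self, gray):
        grid = [2.0, 5.0, 10.0, 20.0, 40.0, 80.0]
        fluxes = [tr.solve_steady_state(gray, tr.GlycemiaScenario(g)).fhex
                  for g in grid]
        assert np.all(np.diff(fluxes) > 0)
        assert all(f < gray.hexokinase.vmax for f in fluxes)
        # approaches Vmax from below at extreme glycemia
        assert fluxes[-1] > 0.95 * gray.hexokinase.vmax


class TestTransient:
    def test_fixed_point_stays(self, gray, gray_steady):
        res = gray_steady
        tra = tr.simulate_transient(gray, tr.EUGLYCEMIA, duration=50.0,
                                    initial_glucose=res.concentrations)
        assert np.allclose(tra.g_in, res.g_in, rtol=2e-3)

    def test_steady_state_invariant_to_volumes(self, gray):
        base = tr.VolumeFractions()
        halved = tr.VolumeFractions(base.blood / 2, base.endothelium / 2,
                                    base.interstice / 2, base.intracellular / 2)
        t1 = tr.simulate_transient(gray, tr.EUGLYCEMIA, base, duration=8000.0)
        t2 = tr.simulate_transient(gray, tr.EUGLYCEMIA, halved, duration=8000.0)
        assert t1.terminal[2] == pytest.approx(t2.terminal[2], rel=1e-4)


class TestCalibration:
    def test_closed_form_vmax(self):
        tissue = tr.calibrate_tissue(1.2, 6.5, 0.05,
                                     tr.GlycemiaScenario.from_mgdl(100.0))
        assert tissue.hexokinase.vmax == pytest.approx(6.5 * 1.25 / 1.2, rel=1e-12)
        assert tissue.hexokinase.vmax == pytest.approx(6.8, rel=5e-3)

    def test_round_trip(self):
        scen = tr.EUGLYCEMIA
        tissue = tr.calibrate_tissue(0.8, 4.0, 0.3, scen)
        res = tr.solve_steady_state(tissue, scen)
        assert res.g_in == pytest.approx(0.8, rel=1e-3)
        assert res.fhex == pytest.approx(4.0, rel=1e-3)

    def test_ratio_preserved_under_uniform_scaling(self):
        tissue = tr.calibrate_tissue(0.5, 3.0, 0.28, tr.EUGLYCEMIA)
        assert tissue.carrier_ratio == pytest.approx((1.0, 1.0, 10.0))

    def test_white_matter_flux_contrast(self, gray_steady):
        white = tr.white_matter()
        res = tr.solve_steady_state(white, tr.EUGLYCEMIA)
        assert gray_steady.fhex / res.fhex == pytest.approx(1.7, rel=1e-3)
        assert res.g_in == pytest.approx(gray_steady.g_in / 3, rel=1e-3)

    def test_infeasible_target_raises(self):
        with pytest.raises(tr.CalibrationError):
            tr.calibrate_tissue(10.0, 6.5, 0.05, tr.EUGLYCEMIA)  # above blood

    def test_json_round_trip(self, tmp_path):
        white = tr.white_matter()
        tr.save_tissue(white, tmp_path / "white.json")
        loaded = tr.load_tissue(tmp_path / "white.json")
        assert loaded == white


class TestSweeps:
    def test_white_matter_hyperglycemia_increase(self):
        """The HK2 tissue responds strongly to the clamp contrast while the
        HK1 tissue barely moves."""
        white = tr.white_matter()
        df = tr.flux_vs_glycemia(
            white, [tr.EUGLYCEMIA.blood_glucose, tr.HYPERGLYCEMIA.blood_glucose])
        assert df["pct_change"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert df["pct_change"].iloc[1] > 30.0

    def test_gray_matter_insensitive_above_5mm(self, gray):
        df = tr.flux_vs_glycemia(gray, [5.0, 30.0],
                                 scenario_eu=tr.GlycemiaScenario(5.0))
        assert df["pct_change"].iloc[1] < 5.0

    def test_sensitivity_grid_monotonicity(self):
        grid = tr.sensitivity_grid((1.0, 2.0, 5.6, 10.0),
                                   (1.0 / 3.0, 0.5, 0.75, 1.0))
        pc = grid.percent_change
        assert grid.failures == ()
        assert np.all(np.isfinite(pc))
        assert np.all(np.diff(pc, axis=0) >= 0)  # non-decreasing in Km
        assert np.all(np.diff(pc, axis=1) <= 0)  # non-increasing in basal G_in

    def test_one_cell_grid_consistent_with_sweep(self, gray_steady):
        grid = tr.sensitivity_grid((5.6,), (1.0 / 3.0,))
        white = tr.white_matter()
        df = tr.flux_vs_glycemia(
            white, [tr.HYPERGLYCEMIA.blood_glucose])
        assert grid.percent_change[0, 0] == pytest.approx(
            df["pct_change"].iloc[0], rel=1e-6)
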