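"""Model equations, fitting protocol and unit conversions.

Hand-derived reference values:
  triplet factor at tau = tau_t, T_t = 0.15: 1 + 0.15 e^-1 / 0.85 = 1.0649199
  3D term at tau = tau_d1, S = 5: 1 / (2 sqrt(1.04)) = 0.4902903
  omega_r = sqrt(4 * 325 um^2/s * 20 us) = 0.161245 um
  D = (0.2 um)^2 / (4 * 32.26 ms) = 0.31002 um^2/s
"""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carscope.fcs_correlate import AutocorrelationCurve
from carscope.fcs_model import (
    CalibrationResult,
    FCSModelParams,
    calibrate_dye,
    calibrate_joint,
    calibrate_ligand,
    component_fraction,
    diffusion_coefficient,
    diffusion_factor,
    diffusion_time,
    fit_cell,
    fit_curve,
    jackknife_membrane_D,
    model_G,
    triplet_factor,
)


class TestTripletFactor:
    def test_zero_fraction_is_unity(self):
        tau = np.logspace(-7, -1, 20)
        np.testing.assert_allclose(triplet_factor(tau, 0.0, 5e-6), 1.0)

    def test_long_lag_limit(self):
        assert triplet_factor(10.0, 0.3, 5e-6) == pytest.approx(1.0, abs=1e-12)

    def test_hand_value_at_tau_t(self):
        assert triplet_factor(5e-6, 0.15, 5e-6) == pytest.approx(1.0649199, abs=1e-6)
        assert triplet_factor(5e-6, 0.15, 5e-6) == pytest.approx(
            1 + 0.15 * math.exp(-1) / 0.85
        )

    @given(
        t_frac=st.floats(0.01, 0.79),
        tau_t=st.floats(1e-6, 1e-4),
    )
    @settings(max_examples=30, deadline=None)
    def test_strictly_decreasing_in_tau(self, t_frac, tau_t):
        # within the resolvable decay range (exp underflows to exactly 1 beyond)
        tau = np.linspace(0.0, 10.0, 50) * tau_t
        vals = triplet_factor(tau, t_frac, tau_t)
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] >= 1.0 - 1e-12

    def test_full_dark_fraction_rejected(self):
        with pytest.raises(ValueError):
            triplet_factor(1e-6, 1.0, 5e-6)


class TestDiffusionFactor:
    def test_zero_lag_equals_amplitude_sum(self):
        p = FCSModelParams(f1=0.4, tau_d1=1e-4, f2=0.6, tau_d2=1e-2, S=4)
        assert diffusion_factor(0.0, p) == pytest.approx(1.0)

    def test_2d_half_decay_at_its_diffusion_time(self):
        p = FCSModelParams(f1=0.0, f2=1.0, tau_d2=1e-2)
        assert diffusion_factor(1e-2, p) == pytest.approx(0.5)

    def test_3d_hand_value_at_tau_d1(self):
        p = FCSModelParams(f1=1.0, tau_d1=1e-4, f2=0.0, S=5)
        assert diffusion_factor(1e-4, p) == pytest.approx(0.4902903, abs=1e-6)

    def test_monotone_decreasing_and_vanishing(self):
        p = FCSModelParams(f1=0.3, tau_d1=1e-4, f2=0.7, tau_d2=1e-2, S=4)
        tau = np.logspace(-7, 1, 100)
        vals = diffusion_factor(tau, p)
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-2

    def test_large_S_limit_reduces_3d_to_2d_form(self):
        # for tau << S^2 tau_d1 the axial factor is ~1 and the 3D term
        # approaches the 2D lineshape
        p3 = FCSModelParams(f1=1.0, tau_d1=1e-3, f2=0.0, S=25.0)
        tau = np.logspace(-6, -1.5, 40)
        v3 = diffusion_factor(tau, p3)
        v2 = 1.0 / (1.0 + tau / 1e-3)
        np.testing.assert_allclose(v3, v2, rtol=0.05)


class TestModelG:
    def test_no_amplitude_gives_flat_unity(self):
        p = FCSModelParams(T_t=0.2, f1=0.0, f2=0.0)
        tau = np.logspace(-7, -1, 30)
        np.testing.assert_allclose(model_G(tau, p), 1.0)

    def test_long_lag_baseline(self):
        p = FCSModelParams(T_t=0.2, f1=0.5, tau_d1=1e-4, f2=0.5, tau_d2=1e-2, S=4)
        assert model_G(100.0, p) == pytest.approx(1.0, abs=1e-4)
        assert model_G(100.0, p) > 1.0  # approaches the baseline from above

    def test_hand_value_2d_only(self):
        p = FCSModelParams(T_t=0.0, f1=0.0, f2=0.1, tau_d2=1e-3)
        assert model_G(1e-3, p) == pytest.approx(1.05)

    def test_reduces_to_single_2d_component(self):
        p = FCSModelParams(T_t=0.0, f1=0.0, f2=0.8, tau_d2=2e-3)
        tau = np.logspace(-6, -1, 30)
        np.testing.assert_allclose(model_G(tau, p), 1 + 0.8 / (1 + tau / 2e-3))


class TestConversions:
    def test_hand_value(self):
        assert diffusion_coefficient(0.03226, 0.2) == pytest.approx(0.3100, abs=2e-4)

    def test_calibration_omega_hand_value(self):
        assert math.sqrt(4 * 325 * 2e-5) == pytest.approx(0.161245, abs=1e-6)

    def test_roundtrip_identity(self):
        for D in (0.31, 0.44, 60.0, 325.0):
            assert diffusion_coefficient(diffusion_time(D, 0.2), 0.2) == pytest.approx(D)

    def test_doubling_omega_quadruples_D(self):
        d1 = diffusion_coefficient(1e-2, 0.2)
        d2 = diffusion_coefficient(1e-2, 0.4)
        assert d2 == pytest.approx(4 * d1)

    @pytest.mark.parametrize("tau,omega", [(0.0, 0.2), (-1e-3, 0.2), (1e-3, 0.0)])
    def test_nonpositive_inputs_rejected(self, tau, omega):
        with pytest.raises(ValueError):
            diffusion_coefficient(tau, omega)


class TestComponentFraction:
    @pytest.mark.parametrize(
        "f1,f2,expected", [(0.0, 0.5, 0.0), (0.2, 0.2, 0.5), (0.03, 0.07, 0.3)]
    )
    def test_values(self, f1, f2, expected):
        p = FCSModelParams(f1=f1, f2=f2)
        assert component_fraction(p) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            component_fraction(FCSModelParams(f1=0.0, f2=0.0))

    @given(f1=st.floats(0, 5), f2=st.floats(0, 5))
    @settings(max_examples=30, deadline=None)
    def test_in_unit_interval_and_complementary(self, f1, f2):
        if f1 + f2 <= 0:
            return
        p = FCSModelParams(f1=f1, f2=f2)
        q = FCSModelParams(f1=f2, f2=f1)
        frac = component_fraction(p)
        assert 0.0 <= frac <= 1.0
        assert component_fraction(q) == pytest.approx(1 - frac)


TRUE_CELL = FCSModelParams(
    T_t=0.15, tau_t=5e-6, f1=0.3, tau_d1=1.6e-4, f2=0.9, tau_d2=2.5e-2, S=4.0
)


class TestFitCurve:
    def test_noiseless_roundtrip_recovers_parameters(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, TRUE_CELL)
        fit = fit_curve(curve, params0=replace(TRUE_CELL, tau_d2=1e-2, f1=0.5, f2=0.5),
                        fixed={"S": True, "tau_d1": True})
        assert fit.success
        assert fit.tau_d2 == pytest.approx(TRUE_CELL.tau_d2, rel=1e-3)
        assert fit.f1 == pytest.approx(TRUE_CELL.f1, rel=1e-2)
        assert fit.f2 == pytest.approx(TRUE_CELL.f2, rel=1e-2)
        assert fit.T_t == pytest.approx(TRUE_CELL.T_t, rel=1e-2)

    def test_fixing_a_parameter_at_truth_leaves_estimates(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, TRUE_CELL)
        free = fit_curve(curve, params0=TRUE_CELL, fixed={"S": True, "tau_d1": True})
        also_f1 = fit_curve(
            curve, params0=TRUE_CELL, fixed={"S": True, "tau_d1": True, "f1": True}
        )
        assert also_f1.f1 == TRUE_CELL.f1  # untouched
        assert also_f1.tau_d2 == pytest.approx(free.tau_d2, rel=1e-3)

    def test_fixed_flags_honored_exactly(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, TRUE_CELL)
        fit = fit_curve(curve, params0=TRUE_CELL, fixed={"tau_d1": True, "S": True})
        assert fit.fixed["tau_d1"] and fit.fixed["S"]
        assert fit.tau_d1 == TRUE_CELL.tau_d1
        assert fit.S == TRUE_CELL.S

    def test_too_few_lags_rejected(self, make_model_curve):
        lags = np.logspace(-6, -2, 12)
        curve = make_model_curve(lags, TRUE_CELL)
        with pytest.raises(ValueError, match="lags"):
            fit_curve(curve)


class TestCalibration:
    DYE = FCSModelParams(T_t=0.15, tau_t=5e-6, f1=3.0, tau_d1=2e-5, f2=0.0, S=4.0)

    def test_calibrate_dye_noiseless(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, self.DYE)
        calib = calibrate_dye(curve, D_reference=325.0)
        assert calib.tau_dye == pytest.approx(2e-5, rel=5e-3)
        assert calib.S == pytest.approx(4.0, rel=0.05)
        assert calib.omega_r == pytest.approx(0.161245, rel=5e-3)

    def test_calibrate_ligand_same_species_matches_dye(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, self.DYE)
        calib = CalibrationResult(omega_r=0.1612, S=4.0, tau_dye=2e-5, D_dye_reference=325.0)
        out = calibrate_ligand(curve, calib)
        assert out.tau_ligand == pytest.approx(2e-5, rel=5e-3)

    def test_calibrate_ligand_five_fold_slower(self, model_lag_grid, make_model_curve):
        ligand = replace(self.DYE, tau_d1=1e-4)  # 5x the dye's diffusion time
        curve = make_model_curve(model_lag_grid, ligand)
        calib = CalibrationResult(omega_r=0.1612, S=4.0, tau_dye=2e-5, D_dye_reference=325.0)
        out = calibrate_ligand(curve, calib)
        assert out.tau_ligand == pytest.approx(5 * calib.tau_dye, rel=1e-2)

    def test_joint_calibration_noiseless(self, model_lag_grid, make_model_curve):
        dye_curve = make_model_curve(model_lag_grid, self.DYE)
        lig_curve = make_model_curve(model_lag_grid, replace(self.DYE, tau_d1=1.6e-4, f1=2.0))
        calib = calibrate_joint(dye_curve, lig_curve, D_reference=325.0)
        assert calib.tau_dye == pytest.approx(2e-5, rel=1e-2)
        assert calib.tau_ligand == pytest.approx(1.6e-4, rel=1e-2)
        assert calib.S == pytest.approx(4.0, rel=0.1)

    def test_joint_calibration_with_fixed_S(self, model_lag_grid, make_model_curve):
        dye_curve = make_model_curve(model_lag_grid, self.DYE)
        lig_curve = make_model_curve(model_lag_grid, replace(self.DYE, tau_d1=1.6e-4, f1=2.0))
        calib = calibrate_joint(dye_curve, lig_curve, S_fixed=4.0)
        assert calib.S == 4.0
        assert calib.tau_dye == pytest.approx(2e-5, rel=1e-2)

    def test_ligand_faster_than_dye_rejected(self):
        with pytest.raises(ValueError, match="ligand"):
            CalibrationResult(
                omega_r=0.16, S=4.0, tau_dye=2e-5, D_dye_reference=325.0, tau_ligand=1e-5
            )


class TestFitCell:
    def make_calib(self):
        return CalibrationResult(
            omega_r=0.2, S=4.0, tau_dye=3.08e-5, D_dye_reference=325.0, tau_ligand=1.6e-4
        )

    def test_noiseless_roundtrip(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, TRUE_CELL)
        calib = self.make_calib()
        fit = fit_cell(curve, calib)
        assert fit.fixed["tau_d1"] and fit.fixed["S"]
        assert fit.tau_d1 == calib.tau_ligand
        assert fit.tau_d2 == pytest.approx(TRUE_CELL.tau_d2, rel=1e-2)
        assert component_fraction(fit) == pytest.approx(
            component_fraction(TRUE_CELL), abs=0.02
        )

    def test_incomplete_calibration_rejected(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, TRUE_CELL)
        calib = CalibrationResult(omega_r=0.2, S=4.0, tau_dye=3e-5, D_dye_reference=325.0)
        with pytest.raises(ValueError, match="calibrat"):
            fit_cell(curve, calib)

    def test_jackknife_on_identical_runs_has_zero_spread(self, model_lag_grid, make_model_curve):
        curve = make_model_curve(model_lag_grid, TRUE_CELL)
        curves = [curve, curve, curve, curve]
        mean, se = jackknife_membrane_D(curves, self.make_calib())
        assert se == pytest.approx(0.0, abs=1e-9)
        assert mean == pytest.approx(
            diffusion_coefficient(TRUE_CELL.tau_d2, 0.2), rel=1e-2
        )


class TestParamsValidation:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FCSModelParams(T_t=1.2)
        with pytest.raises(ValueError):
            FCSModelParams(tau_d2=-1.0)
        with pytest.raises(ValueError):
            FCSModelParams(S=0.5)

    def test_report_serialization(self, tmp_path):
        p = FCSModelParams(f1=0.2, f2=0.8)
        path = tmp_path / "fit.json"
        p.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["f1"] == pytest.approx(0.2)
        assert "fixed" in loaded and "stderr" in loaded
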