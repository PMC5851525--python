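"""DSC models: baselines, integration, excess-Cp shapes, fitting."""

import numpy as np
import pytest

from oligotherm import (
    R_KCAL,
    Thermogram,
    calorimetric_enthalpy,
    dissociative_excess_cp,
    enthalpy_vs_concentration,
    fit_thermogram,
    subtract_baseline,
    two_state_excess_cp,
    vant_hoff_from_peak,
)
from oligotherm.dsc import _midpoint_temperature
from oligotherm.thermo import celsius_to_kelvin as c2k

TM = c2k(102.6)
DH_CAL = 515.0
DH_VH = 214.2


class TestTwoState:
    def test_peak_height_closed_form(self, scan_grid_k):
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        expected = DH_CAL * DH_VH / (4.0 * R_KCAL * TM**2)
        assert trace.excess_cp.max() == pytest.approx(expected, rel=1e-6)
        assert trace.temperature[np.argmax(trace.excess_cp)] == pytest.approx(
            TM, abs=0.1
        )

    def test_area_normalizes_to_calorimetric_enthalpy(self, scan_grid_k):
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        assert calorimetric_enthalpy(trace) == pytest.approx(DH_CAL, rel=0.005)

    def test_vant_hoff_recovered_from_peak_shape(self, scan_grid_k):
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        dh_vh = vant_hoff_from_peak(
            float(trace.excess_cp.max()), TM, calorimetric_enthalpy(trace)
        )
        assert dh_vh == pytest.approx(DH_VH, rel=0.005)

    def test_midpoint_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            two_state_excess_cp(c2k(150.0), DH_VH, DH_CAL, c2k(np.arange(20, 125, 0.1)))


class TestDissociative:
    def test_reduces_to_two_state_at_n_1(self, scan_grid_k):
        d1 = dissociative_excess_cp(1, DH_VH, DH_CAL, TM, 7e-6, scan_grid_k)
        ts = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        scale = ts.excess_cp.max()
        assert np.max(np.abs(d1.excess_cp - ts.excess_cp)) < 1e-6 * scale

    def test_skewed_toward_low_temperature(self, scan_grid_k):
        # dissociation coupling makes the rise below the peak much
        # broader than the drop above it, and places the half-conversion
        # midpoint inside the broad low-temperature wing
        trace = dissociative_excess_cp(16, DH_VH, DH_CAL, TM, 7e-6, scan_grid_k)
        cp, t = trace.excess_cp, trace.temperature
        ipk = int(np.argmax(cp))
        half = cp[ipk] / 2.0
        low_cross = t[: ipk + 1][np.nonzero(cp[: ipk + 1] >= half)[0][0]]
        high_cross = t[ipk:][np.nonzero(cp[ipk:] < half)[0][0]]
        low_width = t[ipk] - low_cross
        high_width = high_cross - t[ipk]
        assert low_width > 2.0 * high_width
        assert TM < t[ipk]  # α = 0.5 midpoint sits in the skewed wing

    def test_alpha_midpoint_at_peak_for_two_state_shape(self, scan_grid_k):
        # sanity contrast: at n = 1 the peak IS the midpoint
        trace = dissociative_excess_cp(1, DH_VH, DH_CAL, TM, 7e-6, scan_grid_k)
        ipk = int(np.argmax(trace.excess_cp))
        assert trace.temperature[ipk] == pytest.approx(TM, abs=0.15)

    def test_apparent_midpoint_increases_with_concentration(self, scan_grid_k):
        mids = []
        for conc in (1.7e-6, 3.5e-6, 7.0e-6):
            trace = dissociative_excess_cp(
                16, DH_VH, DH_CAL, TM, conc, scan_grid_k, tm_ref_conc=7.0e-6
            )
            mids.append(_midpoint_temperature(trace.temperature, trace.excess_cp))
        assert mids[0] < mids[1] < mids[2]

    @pytest.mark.parametrize("n", [1, 2, 16])
    def test_area_normalizes_on_wide_grid(self, n, wide_grid_k):
        trace = dissociative_excess_cp(n, DH_VH, DH_CAL, TM, 7e-6, wide_grid_k)
        assert calorimetric_enthalpy(trace) == pytest.approx(DH_CAL, rel=0.005)

    def test_accepts_oligomer_system(self, scan_grid_k, hexadecamer):
        via_system = dissociative_excess_cp(
            hexadecamer, DH_VH, DH_CAL, TM, 7e-6, scan_grid_k
        )
        via_int = dissociative_excess_cp(16, DH_VH, DH_CAL, TM, 7e-6, scan_grid_k)
        np.testing.assert_array_equal(via_system.excess_cp, via_int.excess_cp)


class TestBaseline:
    def test_idempotent_on_already_baselined_trace(self):
        # windows deep in the tails, where the model trace is truly zero
        grid = c2k(np.arange(20.0, 190.001, 0.1))
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, grid)
        out = subtract_baseline(trace, method="linear")
        assert np.max(np.abs(out.excess_cp - trace.excess_cp)) < 1e-9

    def test_recovers_trace_under_known_linear_ramp(self, scan_grid_k):
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        ramp = 3.0 + 0.05 * (scan_grid_k - scan_grid_k[0])
        raw = Thermogram(scan_grid_k, trace.excess_cp + ramp)
        out = subtract_baseline(raw, method="linear")
        peak = trace.excess_cp.max()
        assert np.max(np.abs(out.excess_cp - trace.excess_cp)) < 0.005 * peak

    @pytest.mark.parametrize("shift", [-2.0, 2.0])
    def test_progress_baseline_beats_linear_on_stepped_trace(self, shift,
                                                             scan_grid_k):
        # post-transition level differs from pre-transition: the
        # progress baseline follows the step, a straight line cannot
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        k = np.exp(-(DH_VH / R_KCAL) * (1.0 / scan_grid_k - 1.0 / TM))
        alpha = k / (1.0 + k)
        raw = Thermogram(scan_grid_k, trace.excess_cp + shift * alpha)
        prog = subtract_baseline(raw, method="progress")
        lin = subtract_baseline(raw, method="linear")
        area_prog = calorimetric_enthalpy(prog)
        area_lin = calorimetric_enthalpy(lin)
        assert abs(area_prog - DH_CAL) < abs(area_lin - DH_CAL)
        if shift < 0:
            # downward step: the tilted line under-subtracts the peak
            assert area_prog <= area_lin

    def test_no_flat_window_raises(self):
        t = c2k(np.linspace(98, 106, 200))  # transition fills the window
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, t)
        with pytest.raises(ValueError, match="flat"):
            subtract_baseline(trace, method="linear")

    def test_unknown_method_rejected(self, scan_grid_k):
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        with pytest.raises(ValueError):
            subtract_baseline(trace, method="spline")


class TestCalorimetricEnthalpy:
    def test_zero_trace_integrates_to_zero(self, scan_grid_k):
        assert calorimetric_enthalpy(
            Thermogram(scan_grid_k, np.zeros_like(scan_grid_k))
        ) == 0.0

    def test_linearity(self, scan_grid_k):
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        doubled = Thermogram(scan_grid_k, 2.0 * trace.excess_cp)
        assert calorimetric_enthalpy(doubled) == pytest.approx(
            2.0 * calorimetric_enthalpy(trace), rel=1e-12
        )


class TestFitThermogram:
    def test_two_state_roundtrip_published_values(self, scan_grid_k):
        trace = two_state_excess_cp(TM, DH_VH, DH_CAL, scan_grid_k)
        fit = fit_thermogram(trace, model="two_state")
        assert fit.tm_celsius == pytest.approx(102.6, abs=0.1)
        assert fit.delta_h_cal == pytest.approx(DH_CAL, rel=0.01)
        assert fit.delta_h_vh == pytest.approx(DH_VH, rel=0.01)
        assert fit.ratio == pytest.approx(2.40, abs=0.03)

    def test_two_state_self_ratio_unity(self, scan_grid_k):
        # a trace whose area equals its van't Hoff enthalpy is two-state
        trace = two_state_excess_cp(TM, 214.2, 214.2, scan_grid_k)
        fit = fit_thermogram(trace, model="two_state")
        assert fit.ratio == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("n", [1, 2, 16])
    def test_dissociative_roundtrip(self, n, wide_grid_k):
        trace = dissociative_excess_cp(n, DH_VH, DH_CAL, TM, 7e-6, wide_grid_k)
        fit = fit_thermogram(trace, model="dissociative", n=n)
        assert fit.converged
        assert fit.tm_kelvin == pytest.approx(TM, abs=0.01 * TM)
        assert fit.delta_h_cal == pytest.approx(DH_CAL, rel=0.01)
        assert fit.delta_h_vh == pytest.approx(DH_VH, rel=0.01)

    def test_dissociative_data_prefer_dissociative_model(self, scan_grid_k):
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(10):
            trace = dissociative_excess_cp(
                16, DH_VH, DH_CAL, TM, 7e-6, scan_grid_k
            )
            noisy = Thermogram(
                scan_grid_k,
                trace.excess_cp
                + rng.normal(0, 0.01 * trace.excess_cp.max(), scan_grid_k.size),
                total_subunit_conc=7e-6,
            )
            rss_d = fit_thermogram(noisy, model="dissociative", n=16).rss
            rss_t = fit_thermogram(noisy, model="two_state").rss
            wins += rss_d < rss_t
        assert wins == 10

    def test_peak_at_boundary_refused(self):
        t = c2k(np.linspace(103.0, 130.0, 300))
        trace = two_state_excess_cp(c2k(103.0), DH_VH, DH_CAL, t)
        with pytest.raises(ValueError, match="boundary"):
            fit_thermogram(trace, model="two_state")


class TestEnthalpyVsConcentration:
    def test_limits(self, hexadecamer):
        out = enthalpy_vs_concentration(hexadecamer, DH_CAL, [1e-12, 1e-2])
        assert out[0][1] == pytest.approx(0.0, abs=1e-6 * DH_CAL)
        assert out[1][1] == pytest.approx(DH_CAL, rel=1e-3)

    def test_published_ladder_is_monotone(self, hexadecamer):
        out = enthalpy_vs_concentration(
            hexadecamer, DH_CAL, [1.7e-6, 3.5e-6, 7.0e-6]
        )
        values = [v for _, v in out]
        assert values[0] < values[1] < values[2]

    def test_nonpositive_concentration_rejected(self, hexadecamer):
        with pytest.raises(ValueError):
            enthalpy_vs_concentration(hexadecamer, DH_CAL, [0.0])


class TestThermogramValidation:
    def test_non_monotone_grid_rejected(self):
        t = np.array([300.0, 301.0, 300.5, 302.0])
        with pytest.raises(ValueError, match="row 2"):
            Thermogram(t, np.zeros(4))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Thermogram(np.array([300.0, 301.0]), np.zeros(3))
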