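"""Two-tissue compartment model, input function, SUV and fractal dimension."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petomics.exceptions import DegenerateFitError, InsufficientDataError, ValidationError
from petomics.kinetics import (
    InputFunction,
    KineticParameters,
    TimeActivityCurve,
    TwoTissueModel,
    default_frame_schedule,
    feng_input_function,
    fit_two_tissue,
    fractal_dimension,
    influx,
    solve_two_tissue,
    suv,
)
from petomics.kinetics import _compartment_curves


class TestInflux:
    @pytest.mark.parametrize(
        "k1,k2,k3,expected",
        [
            (0.1, 0.2, 0.2, 0.05),  # printed-formula evaluation
            (0.3, 0.5, 0.0, 0.0),  # no phosphorylation, no trapping
            (0.3, 0.0, 0.4, 0.3),  # no efflux: everything entering is trapped
            (0.0, 0.0, 0.0, 0.0),  # degenerate denominator convention
        ],
    )
    def test_closed_form(self, k1, k2, k3, expected):
        assert influx(k1, k2, k3) == pytest.approx(expected, abs=1e-15)

    def test_monotonicity(self):
        base = influx(0.2, 0.3, 0.1)
        assert influx(0.25, 0.3, 0.1) > base  # increasing in k1
        assert influx(0.2, 0.3, 0.15) > base  # increasing in k3
        assert influx(0.2, 0.4, 0.1) < base  # decreasing in k2


class TestFengInput:
    def test_zero_at_delay_and_before(self):
        cp = feng_input_function(delay=0.5)
        assert cp(0.5) == pytest.approx(0.0, abs=1e-12)
        assert np.all(cp(np.linspace(0, 0.49, 20)) == 0)

    def test_single_peak_then_monotone_decay(self):
        cp = feng_input_function()
        y = cp.plasma_activity
        peak = int(np.argmax(y))
        after = np.diff(y[peak:])
        assert np.all(after <= 1e-9)

    def test_zero_amplitudes_gives_zero_curve(self):
        cp = feng_input_function(A1=0, A2=0, A3=0)
        assert np.all(cp.plasma_activity == 0)

    def test_invalid_eigenvalue_order_rejected(self):
        with pytest.raises(ValidationError):
            feng_input_function(l1=0.1, l2=0.2, l3=0.3)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            InputFunction(np.array([0.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]))


class TestSolveTwoTissue:
    def test_k1_zero_gives_pure_blood_signal(self, cp):
        p = KineticParameters(0.0, 0.4, 0.1, 0.01, vb=0.1)
        blood_only = KineticParameters(0.0, 0.0, 0.0, 0.0, vb=0.1)
        a = solve_two_tissue(p, cp)
        b = solve_two_tissue(blood_only, cp)
        np.testing.assert_allclose(a.activity, b.activity, rtol=1e-12)

    def test_steady_state_free_compartment(self):
        # constant Cp = c, k4 = 0: C1 equilibrates at k1*c/(k2+k3)
        c, k1, k2, k3 = 5.0, 0.2, 0.3, 0.1
        dt = 0.005
        cp_vals = np.full(int(300 / dt) + 1, c)
        c1, _ = _compartment_curves(k1, k2, k3, 0.0, cp_vals, dt)
        assert c1[-1] == pytest.approx(k1 * c / (k2 + k3), rel=1e-6)

    def test_analytic_matches_stiff_integrator(self, cp):
        rng = np.random.default_rng(1)
        for _ in range(5):
            k = np.exp(rng.uniform(np.log(0.01), np.log(1.0), 4))

            def rhs(t, y):
                return [
                    k[0] * cp(t) - (k[1] + k[2]) * y[0] + k[3] * y[1],
                    k[2] * y[0] - k[3] * y[1],
                ]

            sol = solve_ivp(rhs, (0, 60), [0, 0], method="LSODA", rtol=1e-10,
                            atol=1e-12, dense_output=True)
            fine = np.arange(0, 60.0005, 0.001)
            c1, c2 = _compartment_curves(*k, cp(fine), 0.001)
            t_eval = np.linspace(0.5, 60, 40)
            ana = np.interp(t_eval, fine, c1 + c2)
            num = sol.sol(t_eval).sum(axis=0)
            np.testing.assert_allclose(ana, num, rtol=1e-6, atol=1e-9)

    def test_default_schedule_covers_60_minutes(self):
        mids, durs = default_frame_schedule()
        assert len(mids) == 28
        assert mids[0] - durs[0] / 120 == pytest.approx(0.0)
        assert mids[-1] + durs[-1] / 120 == pytest.approx(60.0)


class TestFit:
    def test_noise_free_round_trip(self, cp):
        truth = KineticParameters(0.15, 0.4, 0.1, 0.01, vb=0.05)
        tac = solve_two_tissue(truth, cp)
        fit = fit_two_tissue(tac, cp, seed=3)
        np.testing.assert_allclose(fit.as_array(), truth.as_array(), rtol=0.01)

    def test_pure_blood_tac_recovers_vb(self, cp):
        blood = KineticParameters(0.0, 0.0, 0.0, 0.0, vb=0.1)
        tac = solve_two_tissue(blood, cp)
        fit = fit_two_tissue(tac, cp, seed=0)
        assert fit.vb == pytest.approx(0.1, abs=0.005)
        assert fit.ki < 1e-4

    def test_all_zero_tac_rejected(self, cp):
        mids, durs = default_frame_schedule()
        tac = TimeActivityCurve(mids, np.zeros(28), durs)
        with pytest.raises(DegenerateFitError):
            fit_two_tissue(tac, cp)

    def test_too_few_frames_rejected(self, cp):
        tac = TimeActivityCurve(np.arange(1.0, 6.0), np.ones(5), np.full(5, 60.0))
        with pytest.raises(InsufficientDataError):
            fit_two_tissue(tac, cp)

    def test_nested_one_tissue_never_beats_full_model(self, cp, typical_tac):
        model = TwoTissueModel(typical_tac, cp)
        full = model.fit(seed=0)
        nested = model.nested_one_tissue_fit(seed=0)
        assert full.rss <= nested.rss + 1e-9

    def test_results_summary_and_ci(self, cp, typical_tac):
        res = TwoTissueModel(typical_tac, cp).fit(seed=0)
        text = res.summary()
        assert "Ki" in text and "k3" in text
        ci = res.conf_int()
        assert list(ci.columns) == ["lower", "upper"]
        assert (ci["upper"] >= ci["lower"]).all()


class TestFractalDimension:
    def test_straight_line_has_dimension_one(self):
        t = np.linspace(0, 60, 500)
        assert fractal_dimension((t, 3.0 * t + 1)) == pytest.approx(1.0, abs=0.05)

    def test_constant_curve_convention(self):
        t = np.linspace(0, 60, 30)
        assert fractal_dimension((t, np.full(30, 4.2))) == 1.0

    def test_bounds_and_scale_invariance(self, rng):
        for _ in range(10):
            t = np.linspace(0, 60, 28)
            y = np.abs(rng.standard_normal(28))
            fd = fractal_dimension((t, y))
            assert 1.0 <= fd <= 2.0
            assert fractal_dimension((t, 7.3 * y)) == pytest.approx(fd, abs=1e-12)

    def test_smooth_monotone_curve_near_one(self, typical_tac):
        fd = fractal_dimension(typical_tac)
        assert 1.0 <= fd <= 1.3

    def test_too_few_frames_rejected(self):
        with pytest.raises(InsufficientDataError):
            fractal_dimension((np.array([0.0, 1, 2]), np.array([0.0, 1, 2])))


class TestSUV:
    def _flat_tac(self, level):
        mids, durs = default_frame_schedule()
        return TimeActivityCurve(mids, np.full(28, level), durs)

    def test_unit_arithmetic(self):
        # 10 kBq/mL at 370 MBq / 74 kg -> dose per gram 5 kBq/g -> SUV 2.0
        assert suv(self._flat_tac(10.0), 370.0, 74.0) == pytest.approx(2.0)

    def test_zero_activity(self):
        assert suv(self._flat_tac(0.0), 370.0, 74.0) == 0.0

    def test_linearity_in_weight(self):
        tac = self._flat_tac(5.0)
        assert suv(tac, 370.0, 148.0) == pytest.approx(2 * suv(tac, 370.0, 74.0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            suv(self._flat_tac(1.0), 370.0, 74.0, window=(70.0, 80.0))
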