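import numpy as np
import pandas as pd
import pytest

from funpace import (Condition, Epoch, GatingModel, ModulationModel,
                     SteadyStateIV, Sweep, Trace, activation_curve,
                     compose_steady_state, delta_v_solve, delta_v_timecourse,
                     find_crossover, fit_boltzmann, fullact_iv, ramp_gv,
                     tail_amplitude)
from funpace.channel import make_protocol, simulate_recording, simulate_sweep
from funpace.if_analysis import (AnalysisError, NoCrossoverError,
                                 ActivationCurve)


def _exp_sweep(amp=5.0, tau=100.0, c=-2.0, dt=0.5, dur=1000.0):
    t = dt * np.arange(int(dur / dt))
    i = c + amp * np.exp(-t / tau)
    tr = Trace(0.0, dt, i, "pA/pF", "tail")
    return Sweep(epochs=[Epoch("tail", dur, level=-70.0)], response=tr)


class TestTailAmplitude:
    def test_exact_exponential(self):
        ta = tail_amplitude(_exp_sweep(amp=5.0, tau=100.0, c=-2.0), 0)
        assert ta.amplitude == pytest.approx(5.0, rel=1e-6)
        assert ta.tau == pytest.approx(100.0, rel=1e-6)
        assert ta.i_inf == pytest.approx(-2.0, abs=1e-6)
        assert not ta.flagged

    def test_negative_amplitude(self):
        ta = tail_amplitude(_exp_sweep(amp=-8.0), 0)
        assert ta.amplitude == pytest.approx(-8.0, rel=1e-6)

    def test_flat_tail_zero(self):
        ta = tail_amplitude(_exp_sweep(amp=0.0), 0)
        assert ta.amplitude == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(AnalysisError):
            tail_amplitude(_exp_sweep(dur=10.0), 0)


class TestActivationCurve:
    def test_noiseless_closure(self, noiseless_two_pulse):
        curve = activation_curve(noiseless_two_pulse)
        fit = fit_boltzmann(curve)
        assert fit.params["v_half"] == pytest.approx(-57.3, abs=0.1)
        assert fit.params["s"] == pytest.approx(9.8, abs=0.1)

    def test_values_in_unit_interval(self, noiseless_two_pulse):
        curve = activation_curve(noiseless_two_pulse)
        assert curve.activation.min() >= 0.0
        assert curve.activation.max() == pytest.approx(1.0)

    def test_monotone_voltage_required(self):
        with pytest.raises(AnalysisError):
            ActivationCurve(voltage=[-120.0, -100.0, -100.0, -80.0],
                            activation=[1.0, 0.8, 0.5, 0.2])

    def test_missing_anchor_rejected(self, model, modulation):
        # prepulses never reach the full-activation voltage
        proto = []
        for v in (-50.0, -65.0, -80.0, -95.0):
            proto.append([Epoch("hold", 300.0, level=-35.0),
                          Epoch("prepulse", 2500.0, level=v),
                          Epoch("tail", 500.0, level=-125.0)])
        rec = simulate_recording(proto, model, modulation, Condition(), 0.0,
                                 None)
        with pytest.raises(AnalysisError):
            activation_curve(rec)


class TestFullactIV:
    def test_noiseless_closure(self, noiseless_two_pulse, noiseless_fullact,
                               model):
        boltz = fit_boltzmann(activation_curve(noiseless_two_pulse))
        fit = fullact_iv(noiseless_fullact, activation=boltz)
        # residual bias from the finite-duration prepulse is < 3 %
        assert fit.params["a"] == pytest.approx(model.a, rel=0.03)
        assert fit.params["v_rev"] == pytest.approx(model.v_rev, abs=1.0)

    def test_uncorrected_fit_runs(self, noiseless_fullact):
        fit = fullact_iv(noiseless_fullact)
        assert fit.params["a"] > 0

    def test_slope_ratio_under_drug(self, noiseless_two_pulse,
                                    noiseless_fullact, model, modulation):
        drug = Condition(tmyx=6.0)
        rec_a = simulate_recording(make_protocol("two_pulse_train"), model,
                                   modulation, drug, 0.0, None)
        rec_f = simulate_recording(make_protocol("fullact_tails"), model,
                                   modulation, drug, 0.0, None)
        b_c = fit_boltzmann(activation_curve(noiseless_two_pulse))
        b_d = fit_boltzmann(activation_curve(rec_a))
        a_c = fullact_iv(noiseless_fullact, activation=b_c).params["a"]
        a_d = fullact_iv(rec_f, activation=b_d).params["a"]
        assert a_d / a_c == pytest.approx(
            modulation.gmax_factor(6.0, "whole_cell"), abs=0.03)


class TestSteadyState:
    CTRL = SteadyStateIV(a=0.328, v_rev=-13.6, v_half=-57.3, s=9.8)
    DRUG = SteadyStateIV(a=0.389, v_rev=-12.7, v_half=-69.2, s=11.3)

    def test_compose(self, noiseless_two_pulse, noiseless_fullact):
        boltz = fit_boltzmann(activation_curve(noiseless_two_pulse))
        lin = fullact_iv(noiseless_fullact, activation=boltz)
        ss = compose_steady_state(boltz, lin)
        assert ss.v_half == boltz.params["v_half"]
        assert ss.a == lin.params["a"]

    def test_evaluation(self):
        # at V = v_half the gate is half open
        v = self.CTRL.v_half
        expected = 0.328 * (v + 13.6) * 0.5
        assert self.CTRL(v) == pytest.approx(expected, rel=1e-9)

    def test_crossover_matches_grid_oracle(self):
        x = find_crossover(self.CTRL, self.DRUG)
        grid = np.linspace(-120.0, -40.0, 1600001)
        oracle = grid[np.argmin(np.abs(self.DRUG(grid) - self.CTRL(grid)))]
        assert x == pytest.approx(oracle, abs=0.02)

    def test_identical_curves_raise(self):
        with pytest.raises(NoCrossoverError):
            find_crossover(self.CTRL, self.CTRL)

    def test_no_crossover_raises(self):
        shifted_up = SteadyStateIV(a=0.328, v_rev=40.0, v_half=-57.3, s=9.8)
        with pytest.raises(NoCrossoverError):
            find_crossover(self.CTRL, shifted_up)


class TestDeltaV:
    CTRL = SteadyStateIV(a=0.328, v_rev=-13.6, v_half=-57.3, s=9.8)

    def test_pure_translation_exact(self):
        # whole-curve translation by -7.3 mV (driving force and gating)
        moved = SteadyStateIV(a=0.328, v_rev=-13.6 - 7.3, v_half=-57.3 - 7.3,
                              s=9.8)
        res = delta_v_solve(self.CTRL, moved, -65.0)
        assert res.delta_v == pytest.approx(-7.3, abs=0.02)

    def test_gating_only_shift_helper(self):
        moved = self.CTRL.shifted(-7.3)
        assert moved.v_half == pytest.approx(-64.6)
        assert moved.v_rev == self.CTRL.v_rev

    def test_underestimates_shift_with_conductance_increase(self):
        drug = SteadyStateIV(a=0.389, v_rev=-12.7, v_half=-69.2, s=11.3)
        res = delta_v_solve(self.CTRL, drug, -65.0)
        # brute-force oracle on a dense grid
        grid = np.linspace(-40.0, 40.0, 800001)
        target = self.CTRL(-65.0)
        oracle = grid[np.argmin(np.abs(drug(-65.0 + grid) - target))]
        assert res.delta_v == pytest.approx(oracle, abs=0.02)
        # the compensation is far smaller than the 11.9 mV gating shift
        assert res.magnitude == pytest.approx(5.1, abs=0.3)
        assert res.magnitude < 11.9

    def test_out_of_range_raises(self):
        far = SteadyStateIV(a=0.328, v_rev=-13.6, v_half=-57.3 - 200.0, s=9.8)
        with pytest.raises(AnalysisError):
            delta_v_solve(self.CTRL, far, -65.0, search_mv=10.0)

    def test_timecourse(self):
        series = pd.DataFrame({
            "time": [0.0, 10.0, 20.0, 30.0, 40.0],
            "step_v": [-65.0, -65.0, -65.0, -72.0, -72.0],
            "amplitude": [-10.0, -10.1, -6.0, -10.05, -9.98],
            "condition": ["control", "control", "drug", "drug", "drug"],
            "compensated": [False, False, False, True, True],
        })
        res = delta_v_timecourse(series)
        assert res.delta_v == pytest.approx(-7.0)
        assert res.method == "timecourse"

    def test_timecourse_missing_column(self):
        with pytest.raises(AnalysisError):
            delta_v_timecourse(pd.DataFrame({"time": [0.0]}))


class TestRampGV:
    def test_noiseless_closure(self, inside_out, modulation):
        sw = simulate_sweep(make_protocol("ramp")[0], inside_out, modulation,
                            Condition(), 0.0, None)
        curve = ramp_gv(sw, v_rev=inside_out.v_rev, g_leak=inside_out.g_leak)
        fit = fit_boltzmann(curve)
        # slow-ramp hysteresis keeps the error below ~1 mV
        assert fit.params["v_half"] == pytest.approx(inside_out.v_half0,
                                                     abs=1.0)

    def test_quasi_steady_violation_warns(self, inside_out, modulation):
        fast = [Epoch("hold", 100.0, level=-35.0),
                Epoch("ramp", 2000.0, ramp=(-35.0, -145.0))]
        sw = simulate_sweep(fast, inside_out, modulation, Condition(), 0.0,
                            None)
        with pytest.warns(RuntimeWarning):
            curve = ramp_gv(sw, v_rev=inside_out.v_rev,
                            g_leak=inside_out.g_leak, gating_model=inside_out)
        assert curve.flags
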