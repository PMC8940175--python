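import numpy as np
import pytest

from funpace import Condition, GatingModel, ModulationModel
from funpace.channel import (effective_half_activation, make_protocol,
                             simulate_recording, simulate_sweep,
                             wholecell_attenuation)


class TestGatingModel:
    def test_y_inf_half_point(self, model):
        assert model.y_inf(-57.3, -57.3) == pytest.approx(0.5)

    def test_y_inf_monotone_decreasing_with_depolarisation(self, model):
        v = np.linspace(-140, 0, 50)
        y = model.y_inf(v, -57.3)
        assert np.all(np.diff(y) < 0)

    def test_tau_bell_peak(self, model):
        assert model.tau(model.v_tau) == pytest.approx(model.tau_max / 2.0)
        assert model.tau(model.v_tau - 40) < model.tau(model.v_tau)
        assert model.tau(model.v_tau + 40) < model.tau(model.v_tau)


class TestModulation:
    def test_hill_shift_saturates(self, modulation):
        k, h = modulation.k_camp, modulation.h_camp
        assert modulation.hill_shift(1e6, k, h) == pytest.approx(
            modulation.delta_max, rel=1e-3)
        assert modulation.hill_shift(0.0, k, h) == 0.0

    def test_k_eff_schild(self, modulation):
        # competitive rightward shift: k_eff(6) / k = 1 + 6 / k_i
        ratio = modulation.k_eff(6.0) / modulation.k_camp
        assert ratio == pytest.approx(1.0 + 6.0 / modulation.k_i, rel=1e-9)

    def test_h_eff_interpolation(self, modulation):
        assert modulation.h_eff(0.0) == pytest.approx(modulation.h_camp)
        assert modulation.h_eff(6.0) == pytest.approx(modulation.h_camp_tmyx)
        mid = modulation.h_eff(3.0)
        assert modulation.h_camp_tmyx < mid < modulation.h_camp

    def test_attenuation_limits(self, modulation):
        full = wholecell_attenuation(modulation, Condition(camp=0.0, tmyx=6.0))
        none = wholecell_attenuation(modulation, Condition(camp=1e5, tmyx=6.0))
        assert full == pytest.approx(1.0, abs=1e-6)
        assert none == pytest.approx(0.0, abs=0.01)


class TestEffectiveHalfActivation:
    def test_wholecell_control(self, model, modulation):
        vh = effective_half_activation(model, modulation, Condition())
        assert vh == pytest.approx(-57.3, abs=1e-9)

    def test_wholecell_drug_shift(self, model, modulation):
        vh = effective_half_activation(model, modulation, Condition(tmyx=6.0))
        assert vh == pytest.approx(-69.2, abs=1e-9)

    def test_insideout_no_camp_no_drug_effect(self, inside_out, modulation):
        base = effective_half_activation(inside_out, modulation, Condition())
        drug = effective_half_activation(inside_out, modulation,
                                         Condition(tmyx=6.0))
        assert drug == pytest.approx(base, abs=1e-9)

    def test_insideout_camp_antagonised(self, inside_out, modulation):
        alone = effective_half_activation(inside_out, modulation,
                                          Condition(camp=1.0))
        comb = effective_half_activation(inside_out, modulation,
                                         Condition(camp=1.0, tmyx=6.0))
        assert comb < alone  # smaller depolarising shift with antagonist

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            Condition(camp=-1.0)


class TestSimulateSweep:
    def test_first_sample_at_steady_state(self, model, modulation):
        proto = [p for p in make_protocol("two_pulse_train")][0]
        sw = simulate_sweep(proto, model, modulation, Condition(), 0.0, None)
        v0 = proto[0].level
        y0 = model.y_inf(v0, -57.3)
        expected = model.a * (v0 - model.v_rev) * y0 + model.g_leak * v0
        assert sw.response.samples[0] == pytest.approx(expected, abs=1e-9)

    def test_constant_epoch_exact_exponential(self, model, modulation):
        from funpace import Epoch
        proto = [Epoch("hold", 100.0, level=-35.0),
                 Epoch("step", 800.0, level=-105.0)]
        sw = simulate_sweep(proto, model, modulation, Condition(), 0.0, None)
        i = sw.epoch_samples(1)
        vh = -57.3
        y0 = model.y_inf(-35.0, vh)
        yinf = model.y_inf(-105.0, vh)
        tau = model.tau(-105.0)
        t = sw.response.dt * np.arange(i.size)
        y = yinf + (y0 - yinf) * np.exp(-t / tau)
        pred = model.a * (-105.0 - model.v_rev) * y + model.g_leak * (-105.0)
        np.testing.assert_allclose(i, pred, atol=1e-9)

    def test_noise_seed_determinism(self, model, modulation):
        proto = make_protocol("step_train")[0]
        a = simulate_sweep(proto, model, modulation, Condition(), 0.3, seed=4)
        b = simulate_sweep(proto, model, modulation, Condition(), 0.3, seed=4)
        np.testing.assert_array_equal(a.response.samples, b.response.samples)

    def test_coarse_dt_warns(self, model, modulation):
        from funpace import Epoch
        proto = [Epoch("step", 100.0, level=20.0)]  # tau ~ 2 ms up here
        with pytest.warns(RuntimeWarning):
            simulate_sweep(proto, model, modulation, Condition(), 0.0, None,
                           dt=5.0)

    def test_recording_sub_seeds_differ(self, model, modulation):
        rec = simulate_recording(make_protocol("step_train") * 2, model,
                                 modulation, Condition(), 0.3, seed=9)
        s0 = rec.sweeps[0].response.samples
        s1 = rec.sweeps[1].response.samples
        assert not np.array_equal(s0, s1)


class TestProtocols:
    def test_names(self):
        for kind in ("two_pulse_train", "step_train", "fullact_tails", "ramp"):
            proto = make_protocol(kind)
            assert len(proto) >= 1

    def test_unknown_protocol(self):
        with pytest.raises(ValueError):
            make_protocol("bogus")

    def test_two_pulse_prepulse_span(self):
        proto = make_protocol("two_pulse_train")
        pre = [e.level for sweep in proto for e in sweep
               if e.label == "prepulse"]
        assert min(pre) <= -125.0
        assert max(pre) >= -35.0 or max(pre) <= -20.0
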