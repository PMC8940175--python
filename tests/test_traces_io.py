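import numpy as np
import pytest

from funpace import Epoch, FormatError, Recording, Sweep, Trace
from funpace.io import (ConfigError, load_config, read_sweep_table,
                        write_sweep_table)


def _trace(n=100, dt=0.5, unit="mV"):
    return Trace(t0=0.0, dt=dt, samples=np.linspace(-60, -40, n), unit=unit,
                 label="t")


class TestTrace:
    def test_basic_properties(self):
        tr = _trace(5, dt=2.0)
        assert tr.times.tolist() == [0.0, 2.0, 4.0, 6.0, 8.0]
        assert tr.duration == pytest.approx(10.0)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            Trace(0.0, -1.0, np.zeros(10), "mV", "t")

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Trace(0.0, 0.5, np.array([0.0, np.nan]), "mV", "t")

    def test_rejects_short(self):
        with pytest.raises(ValueError):
            Trace(0.0, 0.5, np.array([1.0]), "mV", "t")

    def test_rejects_unknown_unit(self):
        with pytest.raises(ValueError):
            Trace(0.0, 0.5, np.zeros(4), "furlong", "t")


class TestEpoch:
    def test_level_xor_ramp(self):
        with pytest.raises(ValueError):
            Epoch("e", 10.0)
        with pytest.raises(ValueError):
            Epoch("e", 10.0, level=-35.0, ramp=(-35.0, -145.0))

    def test_ramp_rate_mv_per_min(self):
        e = Epoch("ramp", 60000.0, ramp=(-35.0, -145.0))
        assert e.ramp_rate == pytest.approx(-110.0)
        assert Epoch("h", 10.0, level=-35.0).ramp_rate is None

    def test_command_sampling(self):
        e = Epoch("h", 5.0, level=-35.0)
        assert np.all(e.command(1.0) == -35.0)
        r = Epoch("r", 4.0, ramp=(0.0, 4.0)).command(1.0)
        assert r.tolist() == [0.0, 1.0, 2.0, 3.0]


class TestSweepRecording:
    def test_duration_mismatch_raises(self):
        with pytest.raises(ValueError):
            Sweep(epochs=[Epoch("h", 10.0, level=-35.0)], response=_trace(100))

    def test_epoch_samples(self):
        tr = Trace(0.0, 1.0, np.arange(10.0), "pA/pF", "t")
        sw = Sweep(epochs=[Epoch("a", 4.0, level=0.0),
                           Epoch("b", 6.0, level=-1.0)], response=tr)
        assert sw.epoch_samples(1).tolist() == [4., 5., 6., 7., 8., 9.]

    def test_recording_mode_validation(self):
        with pytest.raises(ValueError):
            Recording(sweeps=[], mode="voodoo")

    def test_recording_mixed_dt_rejected(self):
        s1 = Sweep(epochs=[], response=_trace(10, dt=0.5))
        s2 = Sweep(epochs=[], response=_trace(10, dt=1.0))
        with pytest.raises(ValueError):
            Recording(sweeps=[s1, s2])


class TestSweepTable:
    def _recording(self):
        epochs = [Epoch("hold", 10.0, level=-35.0),
                  Epoch("ramp", 10.0, ramp=(-35.0, -145.0))]
        tr = Trace(0.0, 0.5, np.sin(np.arange(40) / 3.0), "pA/pF", "sweep")
        return Recording(sweeps=[Sweep(epochs=epochs, response=tr)],
                         condition="ctrl", mode="inside_out",
                         meta={"seed": 7})

    def test_round_trip(self, tmp_path):
        rec = self._recording()
        path = tmp_path / "rec.tsv"
        write_sweep_table(rec, path)
        back = read_sweep_table(path)
        assert back.mode == "inside_out"
        assert back.dt == pytest.approx(rec.dt)
        np.testing.assert_allclose(back.sweeps[0].response.samples,
                                   rec.sweeps[0].response.samples, rtol=1e-6)
        e = back.sweeps[0].epochs[1]
        assert e.ramp == pytest.approx((-35.0, -145.0))

    def test_empty_recording_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            write_sweep_table(Recording(sweeps=[]), tmp_path / "x.tsv")

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# unit=mV\n# mode=whole_cell\ntime\tsweep0\n0\t1\n1\t2\n")
        with pytest.raises(FormatError):
            read_sweep_table(path)

    def test_nonuniform_time_rejected(self, tmp_path):
        rec = self._recording()
        path = tmp_path / "rec.tsv"
        write_sweep_table(rec, path)
        lines = path.read_text().splitlines()
        # corrupt one time stamp
        for i, line in enumerate(lines):
            if not line.startswith(("#", "time")):
                parts = line.split("\t")
                parts[0] = str(float(parts[0]) + 0.2)
                lines[i + 1 if False else i] = "\t".join(parts)
                break
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError):
            read_sweep_table(path)


class TestConfig:
    def test_defaults_filled(self, tmp_path):
        p = tmp_path / "c.toml"
        p.write_text("[simulate_ap]\nseed = 3\n")
        cfg = load_config(p)
        assert cfg["simulate_ap"]["seed"] == 3
        assert cfg["simulate_ap"]["mdp"] == pytest.approx(-60.0)
        assert cfg["simulate_ap"]["rate"] is None

    def test_unknown_key_named(self, tmp_path):
        p = tmp_path / "c.toml"
        p.write_text("[simulate_ap]\nseed = 3\nbogus = 1\n")
        with pytest.raises(ConfigError, match="simulate_ap.bogus"):
            load_config(p)

    def test_unknown_section(self, tmp_path):
        p = tmp_path / "c.toml"
        p.write_text("[nope]\nx = 1\n")
        with pytest.raises(ConfigError, match="nope"):
            load_config(p)

    def test_missing_required(self, tmp_path):
        p = tmp_path / "c.toml"
        p.write_text("[simulate_ap]\nmdp = -58.0\n")
        with pytest.raises(ConfigError, match="seed"):
            load_config(p)

    def test_bad_dose_rejected(self, tmp_path):
        p = tmp_path / "c.toml"
        p.write_text("[hill]\ndoses = [1.0, -2.0]\n")
        with pytest.raises(ConfigError, match="doses"):
            load_config(p)
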