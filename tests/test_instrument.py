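"""Virtual instrument: pump strokes, scheduling, temperature, TDI model."""

import math

import numpy as np
import pytest

from cyclescope.instrument import (
    DeadlockError,
    InstrumentError,
    TDICameraModel,
    VirtualInstrument,
    simulate_temperature_trace,
    tdi_scan,
)
from cyclescope.protocol import (
    ProtocolCommand,
    Recipe,
    Verb,
    parse_recipe,
)


def cmd(verb, arg):
    return ProtocolCommand(Verb(verb), arg)


class TestExecuteCommand:
    def test_single_stroke_for_full_stroke_volume(self, small_config):
        vi = VirtualInstrument(small_config)
        vi.execute_command("A", cmd("PORT", "imaging"))
        vi.execute_command("A", cmd("PUMP", 2000.0))
        strokes = vi.log.filter(verb="STROKE")
        assert len(strokes) == 1  # joined 8x250 µL barrels: 2 mL per stroke

    def test_oversize_volume_splits_into_strokes(self, small_config):
        vi = VirtualInstrument(small_config)
        vi.execute_command("A", cmd("PORT", "imaging"))
        duration = vi.execute_command("A", cmd("PUMP", 3000.0))
        assert len(vi.log.filter(verb="STROKE")) == math.ceil(3000 / 2000)
        assert duration == pytest.approx(3000.0 / small_config.flow_rate * 60)

    def test_pump_without_reagent_errors(self, small_config):
        vi = VirtualInstrument(small_config)
        vi.valves["A"].select(20)  # unassigned port
        with pytest.raises(InstrumentError, match="no reagent"):
            vi.execute_command("A", cmd("PUMP", 100.0))

    def test_pump_zero_rejected_at_validation(self):
        with pytest.raises(Exception):
            ProtocolCommand(Verb.PUMP, 0.0)

    def test_reagent_conservation(self, small_config):
        """Cumulative use per reagent equals the sum of addressed volumes."""
        vi = VirtualInstrument(small_config)
        volumes = {"imaging": [500.0, 250.0], "elution": [1000.0]}
        for reagent, vols in volumes.items():
            for v in vols:
                vi.execute_command("A", cmd("PORT", reagent))
                vi.execute_command("A", cmd("PUMP", v))
        use = vi.flowcells["A"].cumulative_reagent_use
        assert use == {r: sum(v) for r, v in volumes.items()}

    def test_temp_ramp_time_first_order(self, small_config):
        vi = VirtualInstrument(small_config)
        # 25 -> 55 °C, tau 20 s, tolerance 0.5: t = 20 ln(30/0.5)
        d = vi.execute_command("A", cmd("TEMP", 55.0))
        assert d == pytest.approx(20.0 * math.log(30.0 / 0.5))
        assert vi.flowcells["A"].temperature_c == 55.0


class TestScheduler:
    def test_wait_resumes_on_other_flowcells_start(self, small_config):
        cfg_ab = type(small_config)(**{**small_config.__dict__,
                                       "flowcell_ids": ("A", "B")})
        a = Recipe((cmd("WAIT", Verb.IMAG), cmd("IMAG", 1)))
        b = Recipe((cmd("PORT", "imaging"), cmd("PUMP", 500.0),
                    cmd("IMAG", 1)))
        vi = VirtualInstrument(cfg_ab)
        vi.run_experiment({"A": a, "B": b})
        b_imag = vi.log.filter(flowcell="B", verb="IMAG")[0]
        a_imag = vi.log.filter(flowcell="A", verb="IMAG")[0]
        assert a_imag.time_s >= b_imag.time_s  # A starts only after B starts

    def test_imag_never_overlaps_across_flowcells(self, small_config):
        cfg_ab = type(small_config)(**{**small_config.__dict__,
                                       "flowcell_ids": ("A", "B")})
        a = Recipe((cmd("IMAG", 1),))
        b = Recipe((cmd("IMAG", 1),))
        vi = VirtualInstrument(cfg_ab)
        vi.run_experiment({"A": a, "B": b})
        d = vi.imaging_duration_s(1)
        starts = sorted(r.time_s for r in vi.log.filter(verb="IMAG"))
        assert starts[1] >= starts[0] + d  # single optical head

    def test_single_flowcell_sequential_times(self, small_config):
        recipe = parse_recipe("PORT: imaging\nPUMP: 500\nHOLD: 10")
        vi = VirtualInstrument(small_config)
        vi.run_experiment({"A": recipe})
        records = [r for r in vi.log.sorted() if r.verb != "STROKE"]
        assert [r.verb for r in records] == ["PORT", "PUMP", "HOLD"]
        assert records[1].time_s == pytest.approx(2.0)          # valve move
        assert records[2].time_s == pytest.approx(2.0 + 60.0)   # 500 µL @ 500 µL/min

    def test_mutual_wait_deadlocks(self, small_config):
        cfg_ab = type(small_config)(**{**small_config.__dict__,
                                       "flowcell_ids": ("A", "B")})
        a = Recipe((cmd("WAIT", Verb.IMAG), cmd("IMAG", 1)))
        b = Recipe((cmd("WAIT", Verb.IMAG), cmd("IMAG", 1)))
        vi = VirtualInstrument(cfg_ab)
        with pytest.raises(DeadlockError):
            vi.run_experiment({"A": a, "B": b})

    def test_wait_on_verb_never_started_deadlocks(self, small_config):
        cfg_ab = type(small_config)(**{**small_config.__dict__,
                                       "flowcell_ids": ("A", "B")})
        a = Recipe((cmd("WAIT", Verb.TEMP),))
        b = Recipe((cmd("HOLD", 1.0),))
        vi = VirtualInstrument(cfg_ab)
        with pytest.raises(DeadlockError, match="never"):
            vi.run_experiment({"A": a, "B": b})

    def test_log_times_nondecreasing_per_flowcell(self, small_config):
        recipe = parse_recipe(
            "PORT: elution\nPUMP: 500\nHOLD: 1\nPORT: imaging\nPUMP: 250")
        vi = VirtualInstrument(small_config)
        vi.run_experiment({"A": recipe})
        times = [r.time_s for r in vi.log.records if r.flowcell == "A"]
        assert all(t1 >= t0 - 1e-9 for t0, t1 in zip(times, times[1:]))


class TestTemperatureTrace:
    def test_setpoint_schedule_dwell(self):
        """The stage schedule replays 7 setpoints at 90 s dwell each."""
        schedule = [(sp, 90.0) for sp in (25, 35, 45, 55, 25, 55, 25)]
        trace = simulate_temperature_trace(schedule, initial_c=25.0)
        assert trace[-1, 0] == pytest.approx(7 * 90.0)
        assert trace.shape[0] == 7 * 90 + 1

    def test_flat_when_setpoint_equals_initial(self):
        trace = simulate_temperature_trace([(25.0, 90.0)], initial_c=25.0)
        assert np.allclose(trace[:, 1], 25.0)

    def test_step_up_is_monotone_nondecreasing(self):
        trace = simulate_temperature_trace([(55.0, 300.0)], initial_c=25.0)
        temps = trace[:, 1]
        assert np.all(np.diff(temps) >= -1e-12)
        assert temps[-1] == pytest.approx(55.0, abs=0.1)  # ~15 tau elapsed

    def test_out_of_range_setpoint_rejected(self):
        with pytest.raises(ValueError):
            simulate_temperature_trace([(70.0, 90.0)])


class TestTDIScan:
    def test_integration_factor_128_on_uniform_scene(self):
        cam = TDICameraModel(read_noise_dn=0.0)
        scene = np.full((8, 2048), 10.0)
        img = tdi_scan(scene, cam, shot_noise=False)
        assert np.all(img == 1280)  # 128 x per-line signal

    def test_zero_scene_yields_dark_pattern(self):
        levels = (10.0, 10, 10, 10, 10, 10, 10, 18)
        cam = TDICameraModel(group_dark_levels=levels, read_noise_dn=0.0)
        img = tdi_scan(np.zeros((4, 2048)), cam, shot_noise=False)
        means = img.reshape(4, 8, 256).mean(axis=(0, 2))
        assert means == pytest.approx(levels)

    def test_clipping_at_12_bit(self):
        cam = TDICameraModel(read_noise_dn=0.0)
        img = tdi_scan(np.full((2, 2048), 1e6), cam, shot_noise=False)
        assert img.max() == 4095

    def test_narrow_scene_rejected(self):
        with pytest.raises(ValueError, match="narrower"):
            tdi_scan(np.zeros((4, 100)), TDICameraModel())

    def test_seeded_scan_bit_reproducible(self):
        cam = TDICameraModel()
        scene = np.random.default_rng(0).uniform(0, 20, (6, 2048))
        a = tdi_scan(scene, cam, rng_seed=42)
        b = tdi_scan(scene, cam, rng_seed=42)
        assert np.array_equal(a, b)

    def test_snr_gain_vs_single_line(self):
        """TDI output mean is x128 a single-line exposure on the same
        phantom at equal readout noise."""
        cam = TDICameraModel(read_noise_dn=3.0)
        scene = np.full((16, 2048), 5.0)
        tdi = tdi_scan(scene, cam, rng_seed=1).mean()
        single = np.clip(
            np.random.default_rng(1).poisson(scene)
            + np.random.default_rng(2).normal(0, 3.0, scene.shape),
            0, 4095).mean()
        assert tdi / single == pytest.approx(128.0, rel=0.05)
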