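import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaskinner.arena import ArenaGeometry, Quadrant
from aquaskinner.controller import (
    ChannelTimers,
    LightSpec,
    RotationSpec,
    ShockCommand,
    ShockRule,
    ShockTrigger,
    TrialConfig,
    TrialPhase,
    build_phase_schedule,
    evaluate_shock,
    lighting_at,
    quantize_duration,
    rotation_state,
    run_trial,
    yoke,
)
from aquaskinner.tracking import QCFlag, TrackState
from aquaskinner.synthdata import ScriptedSource


def q1_rule(**kw):
    defaults = dict(current_mA=1.2, waveform_hz=100.0, duration_ms=96,
                    delay_s=0.0, refractory_s=10.0)
    defaults.update(kw)
    return ShockRule(trigger=ShockTrigger(in_quadrants=frozenset({Quadrant.Q1})), **defaults)


class TestLightValidation:
    def test_levels_zero_to_ten_accepted(self):
        for lvl in range(11):
            LightSpec(red=(lvl,) * 4, blue=(lvl,) * 4)

    def test_level_eleven_rejected(self):
        with pytest.raises(ValueError):
            LightSpec(blue=(11, 0, 0, 0))

    def test_non_integer_level_rejected(self):
        with pytest.raises(ValueError):
            LightSpec(blue=(2.5, 0, 0, 0))

    def test_yaml_config_rejects_level_eleven(self, tmp_path):
        from aquaskinner.config import load_trial_config

        p = tmp_path / "bad.yaml"
        p.write_text(
            "phases:\n"
            "  - name: a\n"
            "    duration_s: 10\n"
            "    light: {red: [2,2,2,2], blue: [11,0,0,0]}\n"
        )
        with pytest.raises(ValueError):
            load_trial_config(p)


class TestRotation:
    def _phase(self, angle, interval_s=600.0):
        return TrialPhase("p", 3600.0, LightSpec(blue=(8, 0, 0, 0)),
                          RotationSpec(angle_deg=angle, interval_s=interval_s))

    def test_no_event_at_time_zero(self):
        assert rotation_state(0.0, self._phase(90)) == 0
        assert rotation_state(599.9, self._phase(90)) == 0
        assert rotation_state(600.0, self._phase(90)) == 1

    def test_four_quarter_turns_compose_to_identity(self):
        ph = self._phase(90)
        assert lighting_at(ph, 0.0) == lighting_at(ph, 4 * 600.0)

    def test_two_half_turns_compose_to_identity(self):
        ph = self._phase(180)
        assert lighting_at(ph, 0.0) == lighting_at(ph, 2 * 600.0)

    def test_quarter_turn_moves_light_clockwise(self):
        ph = self._phase(90)
        red, blue = lighting_at(ph, 600.0)
        # Q1's blue pattern moves clockwise into the Q4 sector
        assert blue == (0, 0, 0, 8)

    def test_two_rotations_put_q1_lighting_at_q3(self):
        # 25 min with 10-min interval -> k=2 quarter turns
        ph = self._phase(90)
        assert rotation_state(25 * 60.0, ph) == 2
        _, blue = lighting_at(ph, 25 * 60.0)
        assert blue[2] == 8 and blue[0] == 0


class TestQuantizeDuration:
    def test_floor_to_grid(self):
        assert quantize_duration(100) == 96

    def test_minimum_is_one_rotation(self):
        assert quantize_duration(20) == 48

    def test_on_grid_unchanged(self):
        assert quantize_duration(96) == 96

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            quantize_duration(0)

    @given(st.integers(1, 10_000))
    @settings(max_examples=300, deadline=None)
    def test_always_multiple_of_48_and_at_least_48(self, req):
        q = quantize_duration(req)
        assert q >= 48
        assert q % 48 == 0
        assert q <= max(req, 48)


class TestPhaseSchedule:
    def test_default_structure(self):
        sched = build_phase_schedule()
        assert sched.n_phases == 6
        assert sched.rotation_ms == 48
        for sources, sinks in sched.phase_roles():
            assert len(set(sources) | set(sinks)) == 4

    def test_electrode_zero_role_enumeration(self):
        roles = build_phase_schedule().phase_roles()
        as_source = {p for p, (src, _) in enumerate(roles) if 0 in src}
        as_sink = {p for p, (_, snk) in enumerate(roles) if 0 in snk}
        assert as_source == {0, 5}
        assert as_sink == {2, 3}

    def test_every_electrode_balanced_over_rotation(self):
        sched = build_phase_schedule()
        drive = {e: 0 for e in range(6)}
        for sources, sinks in sched.phase_roles():
            for e in sources:
                drive[e] += 1
            for e in sinks:
                drive[e] -= 1
        assert all(v == 0 for v in drive.values())

    def test_odd_electrode_count_rejected(self):
        with pytest.raises(ValueError):
            build_phase_schedule(n_electrodes=5)


class TestEvaluateShock:
    def _accepted_state(self, p=(15.0, 15.0)):
        return TrackState(level=p, trend=(0.0, 0.0), last_raw=p, qc_flag=QCFlag.ACCEPTED)

    def test_refractory_blocks_repeat_shocks(self, geometry):
        rule = q1_rule(refractory_s=10.0)
        phase = TrialPhase("t", 600.0, shock_rules=(rule,))
        timers = ChannelTimers()
        state = self._accepted_state()
        onsets = []
        t = 100.0
        while t < 125.0:
            if evaluate_shock(state, rule, t, timers, phase, t, geometry):
                onsets.append(round(t, 1))
            t += 0.1
        assert onsets == [100.0, 110.0, 120.0]

    def test_delay_postpones_onset(self, geometry):
        rule = q1_rule(delay_s=5.0)
        phase = TrialPhase("t", 600.0, shock_rules=(rule,))
        timers = ChannelTimers()
        safe = TrackState(level=(-15.0, -15.0), trend=(0.0, 0.0),
                          last_raw=(-15.0, -15.0), qc_flag=QCFlag.ACCEPTED)
        onsets = []
        for k in range(150):
            t = 195.0 + 0.1 * k
            state = safe if t < 200.0 else self._accepted_state()
            if evaluate_shock(state, rule, t, timers, phase, t, geometry):
                onsets.append(round(t, 1))
        assert onsets[0] == 205.0

    def test_qc_rejected_tick_never_shocks(self, geometry):
        rule = q1_rule()
        phase = TrialPhase("t", 600.0, shock_rules=(rule,))
        bad = TrackState(level=(15.0, 15.0), trend=(0.0, 0.0),
                         last_raw=(15.0, 15.0), qc_flag=QCFlag.REJECTED_JUMP)
        assert evaluate_shock(bad, rule, 0.0, ChannelTimers(), phase, 0.0, geometry) is None

    def test_trigger_follows_rotated_lighting(self, geometry):
        # punish config-Q1; after one clockwise quarter turn that region
        # sits over physical Q4
        rule = q1_rule()
        phase = TrialPhase("t", 3600.0, LightSpec(), RotationSpec(90, 600.0), (rule,))
        in_q4 = TrackState(level=(15.0, -15.0), trend=(0.0, 0.0),
                           last_raw=(15.0, -15.0), qc_flag=QCFlag.ACCEPTED)
        assert evaluate_shock(in_q4, rule, 10.0, ChannelTimers(), phase, 10.0, geometry) is None
        cmd = evaluate_shock(in_q4, rule, 610.0, ChannelTimers(), phase, 610.0, geometry)
        assert cmd is not None and cmd.duration_ms == 96


class TestShockRuleValidation:
    def test_current_off_grid_rejected(self):
        with pytest.raises(ValueError):
            q1_rule(current_mA=0.3)

    def test_current_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            q1_rule(current_mA=20.2)

    def test_waveform_range(self):
        with pytest.raises(ValueError):
            q1_rule(waveform_hz=5.0)

    def test_duration_off_grid_rejected(self):
        with pytest.raises(ValueError):
            q1_rule(duration_ms=50)


class TestYoke:
    def _cmd(self):
        return ShockCommand(1.2, 100.0, 96)

    def test_off_mode_identity(self):
        cmds = [self._cmd(), None]
        assert yoke(cmds, "off") == cmds

    def test_even_follow_odd_copies_partner(self):
        cmds = [None, self._cmd(), self._cmd(), None]
        out = yoke(cmds, "even_follow_odd")
        assert out[0] == cmds[1] and out[2] == cmds[3]
        assert out[1] == cmds[1] and out[3] == cmds[3]

    def test_unpaired_channels_rejected(self):
        with pytest.raises(ValueError):
            yoke([None], "even_follow_odd")


class TestRunTrial:
    def test_exact_shock_count_for_parked_animal(self, geometry):
        phase = TrialPhase("t", 60.0, shock_rules=(q1_rule(refractory_s=10.0),))
        cfg = TrialConfig(phases=(phase,), tick_rate_hz=10.0, n_channels=1)
        src = ScriptedSource([lambda t: (15.0, 15.0)], tick_rate_hz=10.0)
        df = run_trial(cfg, src)
        # onsets at 0,10,20,30,40,50 s
        assert int(df["shock_on"].sum()) == 6

    def test_safe_trajectory_never_shocked(self, geometry):
        phase = TrialPhase("t", 30.0, shock_rules=(q1_rule(),))
        cfg = TrialConfig(phases=(phase,), tick_rate_hz=10.0, n_channels=2)
        src = ScriptedSource([lambda t: (-15.0, -15.0)] * 2, tick_rate_hz=10.0)
        df = run_trial(cfg, src)
        assert df["shock_on"].sum() == 0
        assert len(df) == 300 * 2

    def test_yoked_channel_mirrors_master_stimuli(self, geometry):
        phase = TrialPhase("t", 30.0, shock_rules=(q1_rule(refractory_s=5.0),))
        cfg = TrialConfig(phases=(phase,), tick_rate_hz=10.0, n_channels=2,
                          yoked_mode="even_follow_odd")
        # odd channel (master) sits in the punished quadrant; even sits safe
        src = ScriptedSource([lambda t: (-15.0, -15.0), lambda t: (15.0, 15.0)],
                             tick_rate_hz=10.0)
        df = run_trial(cfg, src)
        even = df[df.channel == 0].reset_index(drop=True)
        odd = df[df.channel == 1].reset_index(drop=True)
        assert odd["shock_on"].sum() > 0
        assert (even["shock_on"] == odd["shock_on"]).all()

    def test_log_is_byte_identical_across_runs(self, geometry):
        phase = TrialPhase("t", 20.0, LightSpec(blue=(8, 8, 0, 0)),
                           RotationSpec(90, 5.0), (q1_rule(),))
        cfg = TrialConfig(phases=(phase,), tick_rate_hz=10.0, n_channels=2)
        outs = []
        for _ in range(2):
            buf = io.StringIO()
            src = ScriptedSource(
                [lambda t: (10.0 * math.cos(t), 10.0 * math.sin(t))] * 2,
                tick_rate_hz=10.0,
            )
            run_trial(cfg, src, sink=buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_light_levels_logged_are_integers_in_range(self):
        phase = TrialPhase("t", 10.0, LightSpec(red=(2, 2, 2, 2), blue=(8, 0, 0, 10)))
        cfg = TrialConfig(phases=(phase,), tick_rate_hz=10.0)
        src = ScriptedSource([lambda t: (5.0, 5.0)], tick_rate_hz=10.0)
        df = run_trial(cfg, src)
        for col in [f"red_q{i}" for i in range(1, 5)] + [f"blue_q{i}" for i in range(1, 5)]:
            assert df[col].between(0, 10).all()

    def test_phase_sequence_switches_lighting(self):
        p1 = TrialPhase("a", 10.0, LightSpec(blue=(8, 8, 8, 8)))
        p2 = TrialPhase("b", 10.0, LightSpec(blue=(0, 0, 0, 0)))
        cfg = TrialConfig(phases=(p1, p2), tick_rate_hz=10.0)
        src = ScriptedSource([lambda t: (5.0, 5.0)], tick_rate_hz=10.0)
        df = run_trial(cfg, src)
        assert (df[df.time_s < 10.0]["blue_q1"] == 8).all()
        assert (df[df.time_s >= 10.0]["blue_q1"] == 0).all()

    def test_tick_rate_above_device_ceiling_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(phases=(TrialPhase("a", 1.0),), tick_rate_hz=30.0)
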