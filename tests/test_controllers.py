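import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mothnav import (GainTable, RMIController, SCController, SZLController,
                     StimulusSample, fsm_step, make_controller, select_mode,
                     velocity_gain)
from mothnav.controllers import FsmParams, GainBranch
from mothnav.core import ConfigurationError

DT = 0.01


def _sample(t=0.0, left=False, right=False, wind_class="front",
            body=(1.0, 0.0)):
    return StimulusSample(t, left, right, wind_class, body)


def _random_stream(rng, n=2000, p_hit=0.01):
    classes = ("front", "back", "left", "right")
    stream = []
    for k in range(n):
        stream.append(_sample(
            t=(k + 1) * DT,
            left=bool(rng.random() < p_hit),
            right=bool(rng.random() < p_hit),
            wind_class=classes[rng.integers(4)],
        ))
    return stream


class TestVelocityGain:
    @pytest.mark.parametrize("f,mode,kv,kw", [
        (0.0, "active", 129.0, 1.82),
        (0.4, "inactive", 105.0, 2.302),
        (0.7, "active", 166.52, 2.4416),
        (0.4, "active", 150.44, 2.1752),
    ])
    def test_affine_law(self, f, mode, kv, kw, table):
        assert velocity_gain(f, mode, table, clamp=False) == pytest.approx(
            (kv, kw))

    def test_inactive_translational_speed_constant(self, table):
        speeds = {velocity_gain(f, "inactive", table)[0]
                  for f in np.arange(0.0, 2.0, 0.05)}
        assert speeds == {105.0}

    def test_active_low_branch_strictly_increasing(self, table):
        fs = np.linspace(0.0, 0.7, 15)
        kv = [velocity_gain(f, "active", table)[0] for f in fs]
        assert np.all(np.diff(kv) > 0)

    def test_near_continuity_at_breakpoint(self, table):
        lo = velocity_gain(0.7, "active", table, clamp=False)[0]
        hi = velocity_gain(0.7 + 1e-9, "active", table, clamp=False)[0]
        assert abs(lo - hi) <= 1.0  # 166.52 vs 166.2

    def test_printed_variant_keeps_raw_row(self):
        raw = GainTable.paper_printed()
        # raw ordering commands a 246 rad/s gain and negative speeds
        assert velocity_gain(1.0, "active", raw, clamp=False) == pytest.approx(
            (-114.0 - 1.59, 246.0 + 2.81))

    def test_clamping_bounds_everywhere(self, table):
        for f in np.arange(0.0, 5.0, 0.1):
            for mode in ("active", "inactive"):
                kv, kw = velocity_gain(f, mode, table)
                assert table.v_min <= kv <= table.v_max
                assert table.w_min <= kw <= table.w_max

    def test_negative_frequency_rejected(self, table):
        with pytest.raises(ValueError):
            velocity_gain(-0.1, "active", table)

    def test_invalid_clamps_rejected(self):
        with pytest.raises(ConfigurationError):
            GainTable(v_min=300.0, v_max=250.0)


class TestModeSelection:
    def test_odor_with_front_wind_selects_active(self):
        assert select_mode(True, "front") == "active"

    @pytest.mark.parametrize("wc", ["left", "right", "back"])
    def test_odor_with_other_wind_selects_inactive(self, wc):
        assert select_mode(True, wc, prev_mode="active") == "inactive"

    @pytest.mark.parametrize("prev", ["active", "inactive"])
    def test_no_detection_retains_mode(self, prev):
        for wc in ("front", "back", "left", "right"):
            assert select_mode(False, wc, prev_mode=prev) == prev


class TestFsm:
    def _fresh_surge(self):
        ctrl = RMIController()
        state = ctrl.initial_state()
        state, _ = fsm_step(state, True, "front", DT, 1.5)
        return state

    def test_detection_resets_any_state_to_surge(self):
        ctrl = RMIController()
        state = ctrl.initial_state()
        # march to loop
        for _ in range(10_000):
            state, _ = fsm_step(state, False, None, DT, 1.5)
        assert state.fsm == "loop"
        state, _ = fsm_step(state, True, "left", DT, 1.5)
        assert state.fsm == "surge"
        assert state.t_in_state == pytest.approx(DT)
        assert state.zigzag_turns_done == 0
        assert state.last_hit_side == "left"

    def test_surge_lasts_half_second(self):
        state = self._fresh_surge()
        ticks = 1
        while state.fsm == "surge":
            state, _ = fsm_step(state, False, None, DT, 1.5)
            ticks += 1
        assert ticks * DT == pytest.approx(0.5, abs=DT)

    def test_three_alternating_turns_then_loop(self):
        state = self._fresh_surge()
        signs = []
        prev_phase = None
        for _ in range(10_000):
            state, (phase, sign) = fsm_step(state, False, None, DT, 1.5)
            if state.fsm == "loop":
                break
            if state.fsm == "zigzag" and phase == "turn" and prev_phase != "turn":
                signs.append(sign)
            prev_phase = phase
        assert state.fsm == "loop"
        assert signs == [1, -1, 1]  # first turn toward the (frontal) hit side
        assert state.zigzag_turns_done == 3

    def test_loop_keeps_third_turn_sign_forever(self):
        state = self._fresh_surge()
        for _ in range(10_000):
            state, cmd = fsm_step(state, False, None, DT, 1.5)
        assert state.fsm == "loop"
        assert cmd == ("turn", 1)

    def test_first_zigzag_turn_toward_right_hit(self):
        ctrl = RMIController()
        state = ctrl.initial_state()
        state, _ = fsm_step(state, True, "right", DT, 1.5)
        while state.fsm == "surge":
            state, cmd = fsm_step(state, False, None, DT, 1.5)
        assert cmd == ("turn", -1)


class TestRmiPolicy:
    def test_surge_speed_follows_active_law(self, table):
        ctrl = RMIController(table)
        state = ctrl.initial_state()
        # detection with frontal wind: active mode
        state, cmd = ctrl.step(state, _sample(t=DT, left=True, right=True),
                               0.4, DT)
        assert state.mode == "active"
        assert cmd.v == pytest.approx(53.6 * 0.4 + 129.0)  # 150.44

    def test_inactive_surge_speed_constant(self, table):
        ctrl = RMIController(table)
        state = ctrl.initial_state()
        state, cmd = ctrl.step(
            state, _sample(t=DT, left=True, right=True, wind_class="back"),
            0.3, DT)
        assert state.mode == "inactive"
        assert cmd.v == pytest.approx(105.0)

    def test_replay_determinism(self, rng, table):
        stream = _random_stream(rng)
        outputs = []
        for _ in range(2):
            ctrl = RMIController(table)
            state = ctrl.initial_state()
            run = []
            for s in stream:
                state, cmd = ctrl.step(state, s, 0.2, DT)
                run.append((cmd.v, cmd.omega, state.fsm, state.mode))
            outputs.append(run)
        assert outputs[0] == outputs[1]

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_commanded_speed_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        stream = _random_stream(rng, n=500, p_hit=0.05)
        for algo in ("rmi", "szl", "sc"):
            ctrl = make_controller(algo)
            state = ctrl.initial_state()
            fs = rng.random(len(stream)) * 2.0
            for s, f in zip(stream, fs):
                state, cmd = ctrl.step(state, s, float(f), DT)
                assert cmd.v >= 0.0


class TestSzlPolicy:
    def test_constant_speeds(self, rng):
        ctrl = SZLController()
        state = ctrl.initial_state()
        for s in _random_stream(rng, n=3000, p_hit=0.02):
            state, cmd = ctrl.step(state, s, rng.random() * 2, DT)
            assert cmd.v == 150.0
            assert cmd.omega in (0.0, 1.5, -1.5)

    def test_wind_independence_bitwise(self, rng):
        base = _random_stream(rng, n=2000, p_hit=0.02)
        runs = []
        for wc in ("front", "back"):
            ctrl = SZLController()
            state = ctrl.initial_state()
            out = []
            for s in base:
                forced = StimulusSample(s.t, s.left_hit, s.right_hit, wc,
                                        s.wind_vector_body)
                state, cmd = ctrl.step(state, forced, 0.5, DT)
                out.append((cmd.v, cmd.omega))
            runs.append(out)
        assert runs[0] == runs[1]

    def test_rmi_with_degenerate_table_equals_szl(self, rng):
        stream = _random_stream(rng, n=3000, p_hit=0.02)
        fs = rng.random(len(stream)) * 2.0
        rmi = RMIController(GainTable.constant(150.0, 1.5))
        szl = SZLController()
        s1, s2 = rmi.initial_state(), szl.initial_state()
        for s, f in zip(stream, fs):
            s1, c1 = rmi.step(s1, s, float(f), DT)
            s2, c2 = szl.step(s2, s, float(f), DT)
            assert c1 == c2


class TestScPolicy:
    def test_detection_facing_upwind_goes_straight(self):
        ctrl = SCController()
        state = ctrl.initial_state()
        state, cmd = ctrl.step(state, _sample(t=DT, left=True), 0.2, DT)
        assert state.phase == "surge"
        assert cmd.v == 150.0 and cmd.omega == 0.0

    def test_detection_facing_crosswind_turns_upwind(self):
        ctrl = SCController()
        state = ctrl.initial_state()
        # wind arriving from the agent's left: turn CCW to face it
        s = _sample(t=DT, left=True, wind_class="left", body=(0.0, 1.0))
        state, cmd = ctrl.step(state, s, 0.2, DT)
        assert cmd.omega == pytest.approx(1.5)

    def test_cast_leg_durations_double_then_saturate(self):
        ctrl = SCController(initial_leg_duration=1.5, max_leg_duration=6.0)
        state = ctrl.initial_state()
        reversals = []
        prev_sign = state.cast_sign
        # never any odor: cast forever; wind from the left keeps legs aligned
        s = _sample(wind_class="left", body=(0.0, 1.0))
        for k in range(60_000):
            state, _ = ctrl.step(state, s, 0.0, DT)
            if state.cast_sign != prev_sign:
                reversals.append((k + 1) * DT)
                prev_sign = state.cast_sign
        d = np.diff([0.0] + reversals)
        assert len(d) >= 6
        # doubling until the cap, then constant-length sweeps
        assert d[:4] == pytest.approx([1.5, 3.0, 6.0, 6.0], rel=0.05)
        assert d[4:] == pytest.approx(np.full(len(d) - 4, 6.0), rel=0.05)
        assert state.phase == "cast"  # never surged

    def test_no_detection_never_surges(self, rng):
        ctrl = SCController()
        state = ctrl.initial_state()
        for s in _random_stream(rng, n=2000, p_hit=0.0):
            state, _ = ctrl.step(state, s, 0.0, DT)
            assert state.phase == "cast"
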