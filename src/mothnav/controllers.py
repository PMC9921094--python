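"""Navigation policies: RMI, surge-zigzag (SZL) and surge-cast (SC).

All three controllers share the silk-moth behavioural program: a finite
state machine of

* **surge**   — straight run in the detected direction for ~0.5 s after an
  odor onset (with a brief corrective turn toward the antenna that fired),
* **zigzag**  — alternating cross-stream turns (three of them) with straight
  legs in between, used to re-contact a lost plume,
* **loop**    — on the fourth turn, continuous rotation in one direction
  until the next detection.

Any odor onset, in any state, resets the machine to surge.

The RMI controller adds two things on top of this program.  First, a search
*mode* chosen at each detection from the wind's arrival direction: odor with
wind from the front selects the **active** mode, odor with wind from any
other direction the **inactive** mode (the mode persists between
detections).  Second, velocity modulation: the translational and angular
speeds are affine functions of the odor-detection frequency f,

    K_v(f) = a_v * f + b_v        [mm/s]
    K_w(f) = a_w * f + b_w        [rad/s]

with separate coefficient rows per mode and per frequency branch (f <= 0.7
Hz vs f > 0.7 Hz), then clamped to the robot's feasible speed range.  In the
active mode the agent speeds up with plume contact quality up to the 0.7 Hz
breakpoint and slows beyond it; in the inactive mode the translational speed
stays at a constant, deliberate 105 mm/s.

SZL is the same state machine at fixed speeds (150 mm/s, 1.5 rad/s),
ignoring wind entirely.  SC is the flying-insect strategy: turn upwind and
surge on detection, cast crosswind with doubling leg lengths when the plume
is lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ConfigurationError, VelocityCommand
from .sensing import StimulusSample

__all__ = [
    "GainBranch",
    "GainTable",
    "FsmParams",
    "ControllerState",
    "SCState",
    "velocity_gain",
    "select_mode",
    "fsm_step",
    "RMIController",
    "SZLController",
    "SCController",
    "rmi_policy",
    "szl_policy",
    "sc_policy",
    "make_controller",
]

MODES = ("active", "inactive")
FSM_STATES = ("surge", "zigzag", "loop")


@dataclass(frozen=True)
class GainBranch:
    """One coefficient row of the velocity-modulation law."""

    a_v: float  # mm/s per Hz
    a_w: float  # rad/s per Hz
    b_v: float  # mm/s
    b_w: float  # rad/s


@dataclass(frozen=True)
class GainTable:
    """Velocity-modulation coefficients per mode and frequency branch.

    The default table is the robot's calibrated parameter set.  The printed
    source of the active-mode f > 0.7 row transposes two entries, which
    would command negative speeds and a ~246 rad/s turn rate; the default
    here uses the ordering that restores positive speeds and near-continuity
    of K_v at the 0.7 Hz breakpoint (166.52 vs 166.2 mm/s).  The raw printed
    row is available via :meth:`paper_printed`.
    """

    active_low: GainBranch = GainBranch(53.6, 0.888, 129.0, 1.82)
    active_high: GainBranch = GainBranch(-114.0, -1.59, 246.0, 2.81)
    inactive_low: GainBranch = GainBranch(0.0, 1.13, 105.0, 1.85)
    inactive_high: GainBranch = GainBranch(0.0, -1.30, 105.0, 2.34)
    breakpoint: float = 0.7  # Hz
    v_min: float = 50.0      # mm/s
    v_max: float = 250.0     # mm/s
    w_min: float = 0.5       # rad/s
    w_max: float = 3.0       # rad/s

    def __post_init__(self) -> None:
        if not (0 < self.v_min <= self.v_max):
            raise ConfigurationError("require 0 < v_min <= v_max")
        if not (0 < self.w_min <= self.w_max):
            raise ConfigurationError("require 0 < w_min <= w_max")

    @classmethod
    def paper_printed(cls) -> "GainTable":
        """Table with the active f > 0.7 row exactly as printed (anomalous)."""
        return cls(active_high=GainBranch(-114.0, 246.0, -1.59, 2.81))

    @classmethod
    def constant(cls, v: float = 150.0, w: float = 1.5) -> "GainTable":
        """Degenerate table: all slopes zero, constant speeds, wide clamps.

        RMI driven by this table reproduces the SZL baseline exactly.
        """
        b = GainBranch(0.0, 0.0, v, w)
        return cls(active_low=b, active_high=b, inactive_low=b,
                   inactive_high=b, v_min=min(v, 1e-6), v_max=max(v, 1e9),
                   w_min=min(w, 1e-6), w_max=max(w, 1e9))

    def branch(self, f: float, mode: str) -> GainBranch:
        low = f <= self.breakpoint
        if mode == "active":
            return self.active_low if low else self.active_high
        if mode == "inactive":
            return self.inactive_low if low else self.inactive_high
        raise ValueError(f"unknown mode {mode!r}")


def velocity_gain(f: float, mode: str, table: GainTable | None = None,
                  clamp: bool = True) -> tuple[float, float]:
    """Evaluate the modulation law: (K_v in mm/s, K_w in rad/s).

    The branch is selected by f <= breakpoint vs f > breakpoint; the affine
    law is evaluated and, unless ``clamp=False``, the result is clamped to
    [v_min, v_max] x [w_min, w_max].
    """
    if f < 0:
        raise ValueError("odor frequency must be >= 0")
    table = table or GainTable()
    br = table.branch(f, mode)
    k_v = br.a_v * f + br.b_v
    k_w = br.a_w * f + br.b_w
    if clamp:
        k_v = min(max(k_v, table.v_min), table.v_max)
        k_w = min(max(k_w, table.w_min), table.w_max)
    return k_v, k_w


def select_mode(hit: bool, wind_class: str, prev_mode: str = "inactive") -> str:
    """Search-mode rule, evaluated at detection ticks.

    Odor with wind from the front -> active; odor with wind from any other
    direction -> inactive; without a detection the previous mode persists.
    """
    if not hit:
        return prev_mode
    return "active" if wind_class == "front" else "inactive"


@dataclass(frozen=True)
class FsmParams:
    """Timing and geometry of the surge-zigzag-loop program.

    The 0.5 s surge duration and the three-turns-then-loop count are the
    behavioural constants of the program; steer/turn angles and the straight
    leg duration are free geometric choices.
    """

    surge_duration: float = 0.5       # s
    surge_steer_angle: float = math.radians(30.0)
    zigzag_turn_angle: float = math.radians(60.0)
    zigzag_straight_duration: float = 1.0  # s
    n_zigzag_turns: int = 3
    straight_fraction: float = 1.0    # v multiplier while turning


@dataclass
class ControllerState:
    """Mutable state of the surge-zigzag-loop machine (RMI and SZL)."""

    fsm: str = "zigzag"
    mode: str = "inactive"
    t_in_state: float = 0.0
    zigzag_turns_done: int = 0
    turn_sign: int = 1
    last_hit_side: str = "front"
    t_in_leg: float = 0.0
    leg_phase: str = "turn"          # "turn" | "straight"
    turn_angle_left: float = math.radians(60.0)
    prev_left: bool = False
    prev_right: bool = False


def _onset_from_levels(state, sample: StimulusSample) -> tuple[bool, str | None]:
    """Edge-detect raw hit levels against the state's previous tick."""
    left_edge = sample.left_hit and not state.prev_left
    right_edge = sample.right_hit and not state.prev_right
    state.prev_left = sample.left_hit
    state.prev_right = sample.right_hit
    if left_edge and right_edge:
        return True, "front"
    if left_edge:
        return True, "left"
    if right_edge:
        return True, "right"
    return False, None


def fsm_step(state: ControllerState, onset: bool, side: str | None, dt: float,
             omega_mag: float, params: FsmParams | None = None
             ) -> tuple[ControllerState, tuple[str, int]]:
    """Advance the shared state machine one tick.

    Returns the state and a phase command ("straight" | "turn", sign).  Any
    onset resets to surge (timers and the zigzag turn counter cleared, hit
    side recorded).  A surge lasting ``surge_duration`` decays to zigzag;
    each zigzag leg is a fixed-angle turn (completed at the commanded
    angular speed ``omega_mag``) followed by a fixed-duration straight; on
    the expiry of leg ``n_zigzag_turns`` the next turn becomes the loop,
    rotating indefinitely with the third turn's sign.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params or FsmParams()

    if onset:
        state.fsm = "surge"
        state.t_in_state = 0.0
        state.zigzag_turns_done = 0
        state.last_hit_side = side or "front"
        state.turn_sign = -1 if state.last_hit_side == "right" else 1
        state.turn_angle_left = (p.surge_steer_angle
                                 if state.last_hit_side in ("left", "right")
                                 else 0.0)
        state.leg_phase = "turn"

    state.t_in_state += dt

    if state.fsm == "surge":
        if state.t_in_state >= p.surge_duration:
            state.fsm = "zigzag"
            state.t_in_state = 0.0
            state.leg_phase = "turn"
            state.turn_angle_left = p.zigzag_turn_angle
            state.t_in_leg = 0.0
            # first zigzag turn heads toward the last detection side
            state.turn_sign = -1 if state.last_hit_side == "right" else 1
        elif state.turn_angle_left > 0.0:
            state.turn_angle_left -= omega_mag * dt
            return state, ("turn", state.turn_sign)
        else:
            return state, ("straight", 0)

    if state.fsm == "zigzag":
        if state.leg_phase == "turn":
            state.turn_angle_left -= omega_mag * dt
            cmd = ("turn", state.turn_sign)
            if state.turn_angle_left <= 0.0:
                state.leg_phase = "straight"
                state.t_in_leg = 0.0
            return state, cmd
        state.t_in_leg += dt
        if state.t_in_leg >= p.zigzag_straight_duration:
            state.zigzag_turns_done += 1
            if state.zigzag_turns_done >= p.n_zigzag_turns:
                # fourth turn becomes the loop, keeping the third turn's sign
                state.fsm = "loop"
                state.t_in_state = 0.0
            else:
                state.turn_sign = -state.turn_sign
                state.leg_phase = "turn"
                state.turn_angle_left = p.zigzag_turn_angle
        return state, ("straight", 0)

    # loop: constant rotation until the next detection
    return state, ("turn", state.turn_sign)


class RMIController:
    """Robust moth-inspired policy: FSM + mode switching + velocity modulation."""

    name = "rmi"

    def __init__(self, table: GainTable | None = None,
                 params: FsmParams | None = None) -> None:
        self.table = table or GainTable()
        self.params = params or FsmParams()

    def initial_state(self) -> ControllerState:
        return ControllerState(turn_angle_left=self.params.zigzag_turn_angle)

    def step(self, state: ControllerState, sample: StimulusSample, f: float,
             dt: float) -> tuple[ControllerState, VelocityCommand]:
        onset, side = _onset_from_levels(state, sample)
        if onset:
            state.mode = select_mode(True, sample.wind_class, state.mode)
        k_v, k_w = velocity_gain(f, state.mode, self.table)
        state, (phase, sign) = fsm_step(state, onset, side, dt, k_w,
                                        self.params)
        if phase == "straight":
            return state, VelocityCommand(k_v, 0.0)
        v = k_v if state.fsm == "surge" else k_v * self.params.straight_fraction
        return state, VelocityCommand(v, sign * k_w)


class SZLController(RMIController):
    """Surge-zigzag baseline: the same program at fixed 150 mm/s, 1.5 rad/s.

    Implemented as RMI driven by a degenerate gain table, which makes the
    stated equivalence structural: wind and odor frequency cannot influence
    the commands because every coefficient row is identical and flat.
    """

    name = "szl"

    def __init__(self, v: float = 150.0, w: float = 1.5,
                 params: FsmParams | None = None) -> None:
        super().__init__(GainTable.constant(v, w), params)


@dataclass
class SCState:
    """Mutable state of the surge-cast policy."""

    phase: str = "cast"              # "surge" | "cast"
    t_since_hit: float = math.inf
    leg_index: int = 0
    t_in_leg: float = 0.0
    cast_sign: int = 1
    prev_left: bool = False
    prev_right: bool = False
    # kept for log compatibility with the FSM controllers
    mode: str = "inactive"
    fsm: str = "cast"


class SCController:
    """Surge-cast policy: upwind surge on detection, crosswind casting after.

    On an odor onset the agent turns to face upwind (wind class "front") and
    advances; after ``lost_timeout`` seconds without odor it casts: it holds
    a heading perpendicular to the wind, alternating sides, with leg
    durations doubling at every reversal (d, 2d, 4d, ...) up to
    ``max_leg_duration``, after which legs stay at that length so the sweep
    remains bounded.  Without any detection it casts forever.
    """

    name = "sc"

    def __init__(self, v: float = 150.0, w: float = 1.5,
                 lost_timeout: float = 1.0,
                 initial_leg_duration: float = 1.5,
                 max_leg_duration: float = 6.0,
                 heading_tolerance: float = math.radians(10.0)) -> None:
        self.v = v
        self.w = w
        self.lost_timeout = lost_timeout
        self.initial_leg_duration = initial_leg_duration
        self.max_leg_duration = max_leg_duration
        self.heading_tolerance = heading_tolerance

    def initial_state(self) -> SCState:
        return SCState()

    @staticmethod
    def _arrival_bearing(sample: StimulusSample) -> float:
        wx, wy = sample.wind_vector_body
        if wx == 0.0 and wy == 0.0:
            centers = {"front": 0.0, "left": math.pi / 2.0,
                       "right": -math.pi / 2.0, "back": math.pi}
            return centers[sample.wind_class]
        return math.atan2(wy, wx)

    def step(self, state: SCState, sample: StimulusSample, f: float,
             dt: float) -> tuple[SCState, VelocityCommand]:
        onset, _side = _onset_from_levels(state, sample)
        if sample.left_hit or sample.right_hit:
            state.t_since_hit = 0.0
        else:
            state.t_since_hit += dt

        if onset:
            state.phase = "surge"
        elif state.phase == "surge" and state.t_since_hit >= self.lost_timeout:
            state.phase = "cast"
            state.leg_index = 0
            state.t_in_leg = 0.0

        beta = self._arrival_bearing(sample)
        if state.phase == "surge":
            state.fsm = "surge"
            if sample.wind_class == "front":
                return state, VelocityCommand(self.v, 0.0)
            # pivot in place toward the wind: turning CCW (omega > 0)
            # decreases the arrival bearing
            omega = self.w if beta > 0 else -self.w
            return state, VelocityCommand(0.0, omega)

        state.fsm = "cast"
        state.t_in_leg += dt
        leg = min(self.initial_leg_duration * 2 ** state.leg_index,
                  self.max_leg_duration)
        if state.t_in_leg >= leg:
            state.leg_index += 1
            state.cast_sign = -state.cast_sign
            state.t_in_leg = 0.0
        target = state.cast_sign * math.pi / 2.0
        err = math.remainder(beta - target, 2.0 * math.pi)
        if abs(err) > self.heading_tolerance:
            # pivot in place at leg reversals: driving through the U-turn
            # would displace the sweep sideways every reversal
            return state, VelocityCommand(0.0, self.w if err > 0 else -self.w)
        return state, VelocityCommand(self.v, 0.0)


# --- functional wrappers ----------------------------------------------------

def rmi_policy(state: ControllerState, sample: StimulusSample, f: float,
               table: GainTable | None = None, dt: float = 0.01
               ) -> tuple[ControllerState, VelocityCommand]:
    """One RMI tick as a pure function (see :class:`RMIController`)."""
    return RMIController(table).step(state, sample, f, dt)


def szl_policy(state: ControllerState, sample: StimulusSample,
               dt: float = 0.01) -> tuple[ControllerState, VelocityCommand]:
    """One SZL tick as a pure function (see :class:`SZLController`)."""
    return SZLController().step(state, sample, 0.0, dt)


def sc_policy(state: SCState, sample: StimulusSample,
              dt: float = 0.01) -> tuple[SCState, VelocityCommand]:
    """One SC tick as a pure function (see :class:`SCController`)."""
    return SCController().step(state, sample, 0.0, dt)


def make_controller(algorithm: str, table: GainTable | None = None,
                    params: FsmParams | None = None):
    """Instantiate a controller by algorithm id ('rmi', 'szl', 'sc')."""
    algorithm = algorithm.lower()
    if algorithm == "rmi":
        return RMIController(table, params)
    if algorithm == "szl":
        return SZLController(params=params)
    if algorithm == "sc":
        return SCController()
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")
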