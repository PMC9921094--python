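"""Closed-loop simulation: unicycle kinematics and the trial protocol.

A trial runs the sense→decide→act loop at dt = 10 ms (the robot's sensor
sampling period): advance wind and plume, sample the antennae and the wind
class, update the odor-detection frequency, query the policy, integrate the
unicycle.  A trial ends at the first of

* **success**  — the agent's centre comes within 0.1 m of the odor source,
* **exit_field** — the agent leaves the arena rectangle,
* **timeout**  — 3 simulated minutes elapse.

Identical seeds yield bit-identical trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Pose, SimulationFault, VelocityCommand, wrap_angle
from .environment import (FilamentCloud, ScenarioConfig, step_plume, step_wind)
from .sensing import OdorFrequencyEstimator, SensingConfig, sample_sensors

__all__ = [
    "DT",
    "TIME_LIMIT",
    "SUCCESS_RADIUS",
    "TrialResult",
    "integrate_pose",
    "run_trial",
    "run_batch",
]

DT = 0.01              # s, robot sensor sampling period
TIME_LIMIT = 180.0     # s, trial time limit (3 min)
SUCCESS_RADIUS = 0.1   # m

STIMULUS_COLUMNS = ["t", "x", "y", "heading", "left_hit", "right_hit",
                    "wind_class", "f", "state", "mode", "v_cmd", "w_cmd"]


def integrate_pose(pose: Pose, cmd: VelocityCommand, dt: float) -> Pose:
    """Unicycle step: turn first, then advance along the new heading.

    ``cmd.v`` is in mm/s and is converted to metres here.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    heading = wrap_angle(pose.heading + cmd.omega * dt)
    step = cmd.v * 1e-3 * dt
    return Pose(pose.x + step * math.cos(heading),
                pose.y + step * math.sin(heading),
                heading, pose.t + dt)


@dataclass
class TrialResult:
    """Outcome and logs of a single localization trial."""

    outcome: str                      # "success" | "exit_field" | "timeout"
    localization_time: float | None   # s, defined only for success
    trajectory: np.ndarray            # (n, 4): t, x, y, heading
    stimulus_log: list = field(repr=False, default_factory=list)
    seed: int = 0
    n_steps: int = 0
    crosswind_sumsq: float = 0.0      # sum of (y - y_odor)^2 over the log
    y_odor: float = 0.0

    @property
    def success(self) -> bool:
        return self.outcome == "success"

    def stimulus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stimulus_log, columns=STIMULUS_COLUMNS)


def run_trial(scenario: ScenarioConfig, policy, seed: int, *,
              dt: float = DT, time_limit: float = TIME_LIMIT,
              success_radius: float = SUCCESS_RADIUS,
              sensing: SensingConfig | None = None,
              record_trajectory: bool = True,
              record_stimulus: bool = True) -> TrialResult:
    """Run one closed-loop trial and return its result.

    The plume is spun up for ``scenario.spinup`` seconds before the agent is
    released, so the arena already contains an established plume at t = 0
    (as in a physical experiment).  All randomness comes from ``seed``.
    """
    rng = np.random.default_rng(seed)
    sensing = sensing or SensingConfig()
    src_x, src_y = scenario.odor_source
    bounds = scenario.field_bounds

    wind = scenario.initial_wind()
    cloud = FilamentCloud()
    n_spin = int(round(scenario.spinup / dt))
    for _ in range(n_spin):
        wind = step_wind(wind, scenario, dt, rng)
        step_plume(cloud, wind, scenario, dt, rng)

    estimator = OdorFrequencyEstimator(sensing.window, sensing.refractory)
    state = policy.initial_state()
    pose = scenario.start()
    prev_class: str | None = None

    traj = [(pose.t, pose.x, pose.y, pose.heading)] if record_trajectory else []
    stim_rows: list = []
    sumsq = (pose.y - src_y) ** 2
    n_logged = 1

    outcome = None
    loc_time = None
    if pose.distance_to(src_x, src_y) <= success_radius:
        outcome, loc_time = "success", 0.0
    elif not bounds.contains(pose.x, pose.y):
        outcome = "exit_field"

    n_ticks = int(round(time_limit / dt))
    k = 0
    while outcome is None and k < n_ticks:
        k += 1
        wind = step_wind(wind, scenario, dt, rng)
        step_plume(cloud, wind, scenario, dt, rng)
        sample = sample_sensors(pose, cloud, wind, sensing, prev_class,
                                scenario.plume.strength)
        prev_class = sample.wind_class
        f, _onset, _side = estimator.update(sample.t, sample.left_hit,
                                            sample.right_hit)
        state, cmd = policy.step(state, sample, f, dt)
        pose = integrate_pose(pose, cmd, dt)
        pose.t = k * dt  # avoid accumulated float drift in the clock

        if not (math.isfinite(pose.x) and math.isfinite(pose.y)
                and math.isfinite(pose.heading)):
            raise SimulationFault(
                f"non-finite pose at t={pose.t:.2f}s (seed {seed})")

        if record_trajectory:
            traj.append((pose.t, pose.x, pose.y, pose.heading))
        if record_stimulus:
            stim_rows.append((sample.t, pose.x, pose.y, pose.heading,
                              sample.left_hit, sample.right_hit,
                              sample.wind_class, f, state.fsm, state.mode,
                              cmd.v, cmd.omega))
        sumsq += (pose.y - src_y) ** 2
        n_logged += 1

        if pose.distance_to(src_x, src_y) <= success_radius:
            outcome, loc_time = "success", pose.t
        elif not bounds.contains(pose.x, pose.y):
            outcome = "exit_field"

    if outcome is None:
        outcome = "timeout"

    return TrialResult(
        outcome=outcome,
        localization_time=loc_time,
        trajectory=np.asarray(traj),
        stimulus_log=stim_rows,
        seed=seed,
        n_steps=n_logged,
        crosswind_sumsq=sumsq,
        y_odor=src_y,
    )


def run_batch(scenario: ScenarioConfig, policy, n_trials: int,
              base_seed: int, **trial_kwargs) -> list[TrialResult]:
    """Run ``n_trials`` independent trials with seeds base_seed..base_seed+n-1."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return [run_trial(scenario, policy, base_seed + i, **trial_kwargs)
            for i in range(n_trials)]
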