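"""Deterministic miniature fixtures for tests and demos.

Three kinds are available through :func:`make_fixture`:

* ``trajectory`` — a 3-row trajectory whose crosswind RMSE is the
  hand-computed sqrt((0.3^2 + 0.4^2 + 0) / 3) = 0.288675... m.
* ``events``     — a canned binary detection stream (Poisson onsets).
* ``rmi_log``    — a noiseless RMI stimulus log: the controller driven by a
  scripted onset schedule with wind held on the nose, so the logged
  commands lie exactly on the clamped modulation law.

Identical seeds produce byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .agent_sim import DT, STIMULUS_COLUMNS
from .controllers import GainTable, RMIController
from .sensing import OdorFrequencyEstimator, StimulusSample

__all__ = ["make_fixture", "scripted_rmi_log", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("events", "trajectory", "rmi_log")


def _trajectory_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {"t": [0.0, 0.01, 0.02],
         "x": [1.5, 1.49, 1.48],
         "y": [0.3, -0.4, 0.0],
         "heading": [math.pi, math.pi, math.pi]})


def _events_frame(seed: int, rate: float = 1.0,
                  duration: float = 30.0, dt: float = DT) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    p = rate * dt
    left = rng.random(n) < p
    right = rng.random(n) < p
    t = np.round(np.arange(1, n + 1) * dt, 6)
    return pd.DataFrame({"t": t, "left_hit": left.astype(int),
                         "right_hit": right.astype(int)})


def scripted_rmi_log(onset_rates=(0.2, 0.4, 0.6, 0.8, 1.0),
                     segment_duration: float = 20.0,
                     wind_class: str = "front",
                     table: GainTable | None = None,
                     dt: float = DT) -> pd.DataFrame:
    """Drive the RMI controller with a deterministic onset schedule.

    Each segment presents evenly spaced one-tick odor contacts at the given
    onset rate (Hz) with the wind held in the stated class, and every tick
    is logged in the trial-runner's stimulus-log schema.  With the default
    front wind the controller stays in the active mode, so the logged
    (f, v_cmd, w_cmd) samples lie on the clamped modulation law — the
    noiseless input for parameter-recovery analyses.
    """
    ctrl = RMIController(table)
    est = OdorFrequencyEstimator()
    state = ctrl.initial_state()
    rows = []
    t = 0.0
    for rate in onset_rates:
        period = int(round(1.0 / (rate * dt))) if rate > 0 else 0
        n = int(round(segment_duration / dt))
        for k in range(n):
            t += dt
            hit = bool(period) and (k % period == 0)
            f, _, _ = est.update(t, hit, False)
            sample = StimulusSample(t, hit, False, wind_class, (0.05, 0.0))
            state, cmd = ctrl.step(state, sample, f, dt)
            rows.append((t, 0.0, 0.0, 0.0, hit, False, wind_class, f,
                         state.fsm, state.mode, cmd.v, cmd.omega))
    return pd.DataFrame(rows, columns=STIMULUS_COLUMNS)


def make_fixture(kind: str, seed: int = 0, out_dir: str | Path = ".",
                 **kwargs) -> Path:
    """Write one fixture CSV; returns its path."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {FIXTURE_KINDS}, got {kind!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "trajectory":
        df = _trajectory_frame()
    elif kind == "events":
        df = _events_frame(seed, **kwargs)
    else:
        df = scripted_rmi_log(**kwargs)
    path = out_dir / f"fixture_{kind}.csv"
    df.to_csv(path, index=False, float_format="%.6f")
    return path
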