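"""Discrete percepts: bilateral odor hits, detection frequency, wind class.

The physical robot carries two alcohol sensors (left/right of the body axis)
and four partitioned wind sensors that resolve the wind's arrival direction
into front/back/left/right quadrants.  This module reduces the continuous
simulated environment to exactly those percepts:

* a binary odor hit per antenna (concentration above threshold at the sensor
  position),
* a four-way body-frame wind class using the *arrival* convention ("front"
  means the agent faces upwind),
* a sliding-window odor-detection frequency f (Hz) counting detection
  *onsets* — a sustained contact is one event, not many.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

from .core import Pose, WindState
from .environment import FilamentCloud, concentration_at_points

import numpy as np

__all__ = [
    "SensingConfig",
    "StimulusSample",
    "classify_wind_direction",
    "sample_sensors",
    "estimate_odor_frequency",
    "OdorFrequencyEstimator",
]

WIND_CLASSES = ("front", "back", "left", "right")


@dataclass(frozen=True)
class SensingConfig:
    """Sensor geometry and detection parameters.

    threshold       : concentration level counting as a hit (arbitrary units).
    window          : sliding window W for the frequency estimate (s).
    refractory      : per-sensor dead time after an onset (s); one filament
                      crossing therefore produces one event.
    sensor_forward  : antenna offset ahead of the body centre (m).
    sensor_lateral  : antenna offset to each side (m).
    wind_dead_band  : below this wind speed (m/s) the previous wind class is
                      carried over.
    """

    threshold: float = 150.0
    window: float = 5.0
    refractory: float = 0.1
    sensor_forward: float = 0.05
    sensor_lateral: float = 0.03
    wind_dead_band: float = 0.05


@dataclass(frozen=True)
class StimulusSample:
    """Per-tick sensory snapshot handed to the controllers."""

    t: float
    left_hit: bool
    right_hit: bool
    wind_class: str
    wind_vector_body: tuple[float, float]  # arrival convention, m/s


def classify_wind_direction(wind_vector_body: tuple[float, float],
                            prev_class: str | None = None,
                            dead_band: float = 0.0) -> str:
    """Quadrant-classify a body-frame wind arrival vector.

    The vector points from the agent toward where the wind comes from;
    bearing 0 (i.e. +x_body) is "front", +90 deg is "left".  Quadrants are
    centred on the body axes with 45 deg half-width; bearings exactly on a
    45 deg boundary go to the axial classes (front/back).  Below the
    dead-band speed the previous class is returned ("front" if there is
    none).
    """
    wx, wy = wind_vector_body
    speed = math.hypot(wx, wy)
    if speed <= dead_band or speed == 0.0:
        return prev_class if prev_class is not None else "front"
    bearing = math.atan2(wy, wx)
    quarter = math.pi / 4.0
    if -quarter <= bearing <= quarter:
        return "front"
    if bearing >= 3.0 * quarter or bearing <= -3.0 * quarter:
        return "back"
    return "left" if bearing > 0 else "right"


def sensor_positions(pose: Pose, cfg: SensingConfig) -> np.ndarray:
    """World coordinates of the (left, right) antennae, shape (2, 2)."""
    c, s = math.cos(pose.heading), math.sin(pose.heading)
    fx, fy = cfg.sensor_forward, cfg.sensor_lateral
    left = (pose.x + c * fx - s * fy, pose.y + s * fx + c * fy)
    right = (pose.x + c * fx + s * fy, pose.y + s * fx - c * fy)
    return np.array([left, right])


def sample_sensors(pose: Pose, cloud: FilamentCloud, wind: WindState,
                   cfg: SensingConfig | None = None,
                   prev_wind_class: str | None = None,
                   strength: float = 1.0) -> StimulusSample:
    """Evaluate both antennae and the wind class at the current pose."""
    cfg = cfg or SensingConfig()
    if cfg.threshold <= 0:
        raise ValueError("detection threshold must be > 0")
    pos = sensor_positions(pose, cfg)
    conc = concentration_at_points(cloud, pos[:, 0], pos[:, 1], strength)
    left_hit = bool(conc[0] >= cfg.threshold)
    right_hit = bool(conc[1] >= cfg.threshold)

    wx, wy = wind.vector
    # arrival vector (-flow), rotated into the body frame
    c, s = math.cos(-pose.heading), math.sin(-pose.heading)
    ax, ay = -wx, -wy
    body = (c * ax - s * ay, s * ax + c * ay)
    wind_class = classify_wind_direction(body, prev_wind_class,
                                         cfg.wind_dead_band)
    return StimulusSample(pose.t, left_hit, right_hit, wind_class, body)


def estimate_odor_frequency(event_times, t_now: float, window: float) -> float:
    """Onsets in (t_now - window, t_now] divided by the window length (Hz)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    lo = t_now - window
    return sum(1 for t in event_times if lo < t <= t_now) / window


class OdorFrequencyEstimator:
    """Streaming onset detector + sliding-window frequency estimate.

    Feed raw per-tick hit levels with :meth:`update`; an onset is a
    false→true transition on either sensor, subject to a per-sensor
    refractory period.  Simultaneous left+right onsets count as a single
    (frontal) event.  The estimate has resolution 1/window Hz.
    """

    def __init__(self, window: float = 5.0, refractory: float = 0.1) -> None:
        if window <= 0:
            raise ValueError("window must be > 0")
        self.window = window
        self.refractory = refractory
        self._events: deque[float] = deque()
        self._prev = [False, False]
        self._last_onset = [-math.inf, -math.inf]

    def update(self, t: float, left_hit: bool, right_hit: bool
               ) -> tuple[float, bool, str | None]:
        """Ingest one tick; return (f, onset_occurred, onset_side)."""
        onsets = []
        for i, hit in enumerate((left_hit, right_hit)):
            if hit and not self._prev[i] and t - self._last_onset[i] >= self.refractory:
                self._last_onset[i] = t
                onsets.append(i)
            self._prev[i] = hit
        onset = bool(onsets)
        side = None
        if onset:
            self._events.append(t)
            side = "front" if len(onsets) == 2 else ("left" if onsets[0] == 0
                                                     else "right")
        lo = t - self.window
        ev = self._events
        while ev and ev[0] <= lo:
            ev.popleft()
        return len(ev) / self.window, onset, side

    @property
    def event_times(self) -> tuple[float, ...]:
        return tuple(self._events)
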