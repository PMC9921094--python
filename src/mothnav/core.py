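"""Shared primitives: poses, wind state, velocity commands, angle helpers.

Conventions used throughout the package:

* World frame: x/y in metres, angles in radians, counter-clockwise positive,
  0 rad pointing along +x.
* ``WindState.direction`` is the direction of *flow* (where the air is going).
  The sensing layer converts this to the arrival convention (where the wind
  comes from) before classifying it, because that is what an on-board wind
  sensor reports.
* Controller commands are expressed in the robot's native units, mm/s and
  rad/s; kinematic integration converts to SI at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

TWO_PI = 2.0 * math.pi


def wrap_angle(a: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    a = (a + math.pi) % TWO_PI - math.pi
    if a == -math.pi:
        a = math.pi
    return a


@dataclass
class Pose:
    """Agent position (m), heading (rad, wrapped to (-pi, pi]) and time (s)."""

    x: float
    y: float
    heading: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.heading = wrap_angle(self.heading)

    def distance_to(self, x: float, y: float) -> float:
        return math.hypot(self.x - x, self.y - y)


@dataclass
class WindState:
    """Spatially uniform instantaneous wind: flow direction (rad) and speed (m/s)."""

    direction: float
    speed: float

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("wind speed must be >= 0")

    @property
    def vector(self) -> tuple[float, float]:
        """Flow vector (m/s) in the world frame."""
        return (self.speed * math.cos(self.direction),
                self.speed * math.sin(self.direction))


@dataclass(frozen=True)
class VelocityCommand:
    """Translational speed v (mm/s) and signed angular rate omega (rad/s)."""

    v: float
    omega: float


class ConfigurationError(ValueError):
    """Raised for invalid scenario / controller configuration values."""


class SimulationFault(RuntimeError):
    """Raised when the closed-loop integration produces a non-finite pose."""
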