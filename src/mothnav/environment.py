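"""Synthetic wind fields and an intermittent filament-based odor plume.

The experimental arenas are emulated by three scenario presets:

* ``scenario_a`` — indoor, fan at (-0.5, 0) blowing along +x, agent starts on
  the plume centerline at (1.5, 0).
* ``scenario_b`` — indoor, fan at (0, -0.3) blowing along +y so the plume is
  displaced off the +x axis; agent starts at (1.5, 0.3).
* ``scenario_c`` — outdoor regime: same geometry as A but with strong,
  gusty wind (large direction/speed fluctuations); agent starts at (1.5, 0.3).

Wind is spatially uniform per tick and evolves as an Ornstein-Uhlenbeck
process around the scenario mean (direction and speed independently), so the
zero-turbulence limit is exactly constant wind.  Odor is a train of Gaussian
puffs ("filaments") released from the source at a fixed rate, advected by the
instantaneous wind with a small diffusive jitter, growing linearly in spread
and pruned once far outside the field.  The resulting concentration field is
intermittent at a fixed sensor: detection frequency falls off with crosswind
offset and with distance from the source, which is the feature the
frequency-modulated controller feeds on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ConfigurationError, Pose, WindState, wrap_angle

__all__ = [
    "Turbulence",
    "PlumeConfig",
    "FieldBounds",
    "ScenarioConfig",
    "FilamentCloud",
    "step_wind",
    "step_plume",
    "concentration_at",
    "scenario_a",
    "scenario_b",
    "scenario_c",
    "get_scenario",
]


@dataclass(frozen=True)
class Turbulence:
    """Stationary statistics of the wind fluctuations.

    ``direction_sd`` (rad) and ``speed_sd`` (m/s) are the stationary standard
    deviations of the OU perturbations; ``correlation_time`` (s) their common
    autocorrelation time.
    """

    direction_sd: float = 0.0
    speed_sd: float = 0.0
    correlation_time: float = 2.0


@dataclass(frozen=True)
class PlumeConfig:
    """Gaussian-puff plume parameters.

    release_rate : puffs released per second (deterministic schedule).
    sigma0       : initial puff spread (m).
    growth_rate  : d sigma / dt (m/s).
    jitter_sd    : per-axis diffusive jitter SD, scaled by sqrt(dt) (m·s^-1/2).
    strength     : kernel weight q; concentration peak of a puff is q/sigma^2.
    """

    release_rate: float = 10.0
    sigma0: float = 0.02
    growth_rate: float = 0.005
    jitter_sd: float = 0.02
    strength: float = 1.0


@dataclass(frozen=True)
class FieldBounds:
    """Axis-aligned rectangular arena (m). Leaving it ends a trial."""

    x_min: float = -0.5
    x_max: float = 2.0
    y_min: float = -1.0
    y_max: float = 1.0

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class ScenarioConfig:
    """Geometry and environmental statistics of one experimental scenario."""

    name: str = "scenario_a"
    odor_source: tuple[float, float] = (0.0, 0.0)
    wind_source: tuple[float, float] = (-0.5, 0.0)
    wind_speed: float = 1.0
    turbulence: Turbulence = field(default_factory=Turbulence)
    field_bounds: FieldBounds = field(default_factory=FieldBounds)
    start_pose: tuple[float, float, float] = (1.5, 0.0, math.pi)
    plume: PlumeConfig = field(default_factory=PlumeConfig)
    mean_wind: tuple[float, float] | None = None
    spinup: float = 5.0

    def __post_init__(self) -> None:
        if self.wind_speed <= 0:
            raise ConfigurationError("wind_speed must be > 0")
        if not self.field_bounds.contains(*self.odor_source):
            raise ConfigurationError("odor_source must lie inside field_bounds")
        if self.turbulence.correlation_time <= 0:
            raise ConfigurationError("turbulence correlation_time must be > 0")

    @property
    def mean_wind_vector(self) -> tuple[float, float]:
        """Mean flow vector (m/s): from the wind source toward the field.

        Unless overridden, the mean direction is the unit vector from the
        wind source to the odor source, scaled by ``wind_speed`` — the fan
        blows across the arena through the source.
        """
        if self.mean_wind is not None:
            return self.mean_wind
        dx = self.odor_source[0] - self.wind_source[0]
        dy = self.odor_source[1] - self.wind_source[1]
        norm = math.hypot(dx, dy)
        if norm == 0:
            raise ConfigurationError("wind_source must differ from odor_source")
        return (self.wind_speed * dx / norm, self.wind_speed * dy / norm)

    @property
    def mean_wind_direction(self) -> float:
        wx, wy = self.mean_wind_vector
        return math.atan2(wy, wx)

    @property
    def mean_wind_speed(self) -> float:
        wx, wy = self.mean_wind_vector
        return math.hypot(wx, wy)

    def initial_wind(self) -> WindState:
        return WindState(self.mean_wind_direction, self.mean_wind_speed)

    def start(self) -> Pose:
        x, y, heading = self.start_pose
        return Pose(x, y, heading, 0.0)


def step_wind(state: WindState, scenario: ScenarioConfig, dt: float,
              rng: np.random.Generator) -> WindState:
    """Advance the uniform wind one tick.

    Direction and speed follow independent OU processes around the scenario
    mean, discretised exactly: x' = mu + (x - mu)·e^(-dt/tau) +
    sd·sqrt(1 - e^(-2 dt/tau))·N(0,1), so ``sd`` is the stationary SD.
    With both SDs zero the wind is constant.  Speed is floored at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tb = scenario.turbulence
    if tb.correlation_time <= 0:
        raise ConfigurationError("turbulence correlation_time must be > 0")
    alpha = math.exp(-dt / tb.correlation_time)
    noise = math.sqrt(max(0.0, 1.0 - alpha * alpha))

    dir_dev = wrap_angle(state.direction - scenario.mean_wind_direction) * alpha
    if tb.direction_sd > 0:
        dir_dev += tb.direction_sd * noise * rng.standard_normal()

    spd_dev = (state.speed - scenario.mean_wind_speed) * alpha
    if tb.speed_sd > 0:
        spd_dev += tb.speed_sd * noise * rng.standard_normal()

    return WindState(
        wrap_angle(scenario.mean_wind_direction + dir_dev),
        max(0.0, scenario.mean_wind_speed + spd_dev),
    )


class FilamentCloud:
    """Mutable collection of odor puffs, stored as flat numpy arrays.

    ``x``/``y`` are centre coordinates (m), ``sigma`` the current Gaussian
    spread (m).  The release accumulator guarantees a deterministic puff
    count: after t seconds exactly floor(rate·t) puffs have been released.
    """

    __slots__ = ("x", "y", "sigma", "_release_acc")

    def __init__(self) -> None:
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.sigma = np.empty(0)
        self._release_acc = 0.0

    def __len__(self) -> int:
        return self.x.size

    def copy(self) -> "FilamentCloud":
        c = FilamentCloud()
        c.x = self.x.copy()
        c.y = self.y.copy()
        c.sigma = self.sigma.copy()
        c._release_acc = self._release_acc
        return c


def step_plume(cloud: FilamentCloud, wind: WindState, scenario: ScenarioConfig,
               dt: float, rng: np.random.Generator,
               prune: bool = True) -> FilamentCloud:
    """Advance the puff cloud one tick (in place; the cloud is also returned).

    Existing puffs advect by wind·dt plus N(0, jitter_sd·sqrt(dt)) per axis
    and grow by growth_rate·dt; new puffs appear at the source on the
    deterministic release schedule; puffs further than 3·sigma outside the
    field are pruned.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pc = scenario.plume
    if pc.release_rate < 0:
        raise ConfigurationError("release_rate must be >= 0")

    n = cloud.x.size
    if n:
        wx, wy = wind.vector
        js = pc.jitter_sd * math.sqrt(dt)
        if js > 0:
            cloud.x += wx * dt + js * rng.standard_normal(n)
            cloud.y += wy * dt + js * rng.standard_normal(n)
        else:
            cloud.x += wx * dt
            cloud.y += wy * dt
        cloud.sigma += pc.growth_rate * dt

    cloud._release_acc += pc.release_rate * dt
    k = int(cloud._release_acc + 1e-9)
    if k:
        cloud._release_acc -= k
        sx, sy = scenario.odor_source
        cloud.x = np.concatenate([cloud.x, np.full(k, sx)])
        cloud.y = np.concatenate([cloud.y, np.full(k, sy)])
        cloud.sigma = np.concatenate([cloud.sigma, np.full(k, pc.sigma0)])

    if prune and cloud.x.size:
        b = scenario.field_bounds
        m = cloud.sigma * 3.0
        keep = ((cloud.x > b.x_min - m) & (cloud.x < b.x_max + m)
                & (cloud.y > b.y_min - m) & (cloud.y < b.y_max + m))
        if not keep.all():
            cloud.x = cloud.x[keep]
            cloud.y = cloud.y[keep]
            cloud.sigma = cloud.sigma[keep]
    return cloud


def concentration_at(cloud: FilamentCloud, p: tuple[float, float],
                     strength: float = 1.0) -> float:
    """Instantaneous concentration (arbitrary units) at a point.

    Sum of Gaussian kernels q·exp(-|p-c|^2 / (2 sigma^2)) / sigma^2 over all
    puffs: non-negative, additive and continuous in p.
    """
    if cloud.x.size == 0:
        return 0.0
    d2 = (cloud.x - p[0]) ** 2 + (cloud.y - p[1]) ** 2
    s2 = cloud.sigma ** 2
    return float(strength * np.sum(np.exp(-d2 / (2.0 * s2)) / s2))


def concentration_at_points(cloud: FilamentCloud, xs: np.ndarray,
                            ys: np.ndarray, strength: float = 1.0) -> np.ndarray:
    """Vectorised :func:`concentration_at` for several query points."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if cloud.x.size == 0:
        return np.zeros(xs.shape)
    d2 = (cloud.x - xs[..., None]) ** 2 + (cloud.y - ys[..., None]) ** 2
    s2 = cloud.sigma ** 2
    return strength * np.sum(np.exp(-d2 / (2.0 * s2)) / s2, axis=-1)


# --- scenario presets -------------------------------------------------------

_INDOOR = Turbulence(direction_sd=0.1, speed_sd=0.05, correlation_time=2.0)
_OUTDOOR = Turbulence(direction_sd=0.5, speed_sd=0.3, correlation_time=2.0)


def scenario_a(**overrides) -> ScenarioConfig:
    """Indoor, wind and odor source aligned; agent starts on the centerline."""
    cfg = ScenarioConfig(
        name="scenario_a",
        wind_source=(-0.5, 0.0),
        start_pose=(1.5, 0.0, math.pi),
        turbulence=_INDOOR,
    )
    return replace(cfg, **overrides) if overrides else cfg


def scenario_b(**overrides) -> ScenarioConfig:
    """Indoor, fan at (0, -0.3) blowing +y: plume displaced off the +x axis."""
    cfg = ScenarioConfig(
        name="scenario_b",
        wind_source=(0.0, -0.3),
        start_pose=(1.5, 0.3, math.pi),
        turbulence=_INDOOR,
    )
    return replace(cfg, **overrides) if overrides else cfg


def scenario_c(**overrides) -> ScenarioConfig:
    """Outdoor regime: geometry of A, strong gusty wind, offset start."""
    cfg = ScenarioConfig(
        name="scenario_c",
        wind_source=(-0.5, 0.0),
        start_pose=(1.5, 0.3, math.pi),
        turbulence=_OUTDOOR,
    )
    return replace(cfg, **overrides) if overrides else cfg


_PRESETS = {"a": scenario_a, "b": scenario_b, "c": scenario_c,
            "scenario_a": scenario_a, "scenario_b": scenario_b,
            "scenario_c": scenario_c}


def get_scenario(name: str, **overrides) -> ScenarioConfig:
    """Look up a scenario preset by name ('a', 'b', 'c')."""
    try:
        factory = _PRESETS[name.lower()]
    except KeyError:
        raise ConfigurationError(f"unknown scenario {name!r}") from None
    return factory(**overrides)
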