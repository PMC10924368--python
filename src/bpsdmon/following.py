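"""Person-following controllers.

Three strategies, all of which stop dead whenever the target is not
detected:

1. fixed-distance proportional follower;
2. distance-band follower (moves only when outside a [min, max] band,
   trading tracking tightness for power);
3. adaptive follower whose desired distance comes from a Mamdani fuzzy
   controller over (target speed, deviation from vision center): the
   faster the target, or the larger the deviation, the closer the robot
   follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .perception import TrackEstimator
from .simulation import Room, SensorReading, SimConfig

__all__ = [
    "FollowCommand",
    "ControlGains",
    "FuzzyConfig",
    "algorithm1_step",
    "algorithm2_step",
    "algorithm3_step",
    "fuzzy_desired_distance",
    "Algorithm1",
    "Algorithm2",
    "Algorithm3",
    "make_follower",
]

STOP = None  # placeholder; real constant defined after FollowCommand


@dataclass(frozen=True)
class FollowCommand:
    """Linear (m/s) and angular (rad/s) velocity command."""

    v: float
    w: float


STOP = FollowCommand(0.0, 0.0)


@dataclass(frozen=True)
class ControlGains:
    """Proportional gains for the distance/bearing servo loops.

    Values are package defaults (the source describes the controllers only
    qualitatively): distance gain 2.0 1/s, bearing gain 3.0 1/s, both
    saturated by the robot's velocity limits.
    """

    kp_dist: float = 2.0
    kp_bearing: float = 3.0
    max_v: float = SimConfig.max_v
    max_w: float = SimConfig.max_w


def _servo(reading: SensorReading, desired: float, g: ControlGains) -> FollowCommand:
    v = float(np.clip(g.kp_dist * (reading.distance - desired), -g.max_v, g.max_v))
    w = float(np.clip(g.kp_bearing * reading.bearing, -g.max_w, g.max_w))
    return FollowCommand(v, w)


def algorithm1_step(
    reading: SensorReading, target_distance: float, gains: ControlGains | None = None
) -> FollowCommand:
    """Follow at a fixed distance; stop while the target is undetected."""
    if not reading.visible:
        return STOP
    return _servo(reading, target_distance, gains or ControlGains())


def algorithm2_step(
    reading: SensorReading,
    bounds: tuple[float, float],
    gains: ControlGains | None = None,
) -> FollowCommand:
    """Keep the distance within a band; idle (turn only) while inside it."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"bounds must satisfy min < max, got {bounds}")
    if not reading.visible:
        return STOP
    g = gains or ControlGains()
    if reading.distance > hi:
        return _servo(reading, hi, g)
    if reading.distance < lo:
        return _servo(reading, lo, g)
    w = float(np.clip(g.kp_bearing * reading.bearing, -g.max_w, g.max_w))
    return FollowCommand(0.0, w)


# ---------------------------------------------------------------------------
# fuzzy controller
# ---------------------------------------------------------------------------


def _tri(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Triangular membership with feet a, c and peak b; the end terms
    saturate at the universe edges (shoulder shape)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if b > a:
        rising = (x >= a) & (x <= b)
        out[rising] = (x[rising] - a) / (b - a)
    else:
        out[x <= b] = 1.0
    if c > b:
        falling = (x > b) & (x <= c)
        out[falling] = (c - x[falling]) / (c - b)
    else:
        out[x >= b] = 1.0
    return out


@dataclass
class FuzzyConfig:
    """Universes, membership break points, and the 3x3 rule table.

    Inputs: target speed on [0, 1.3] m/s with terms SS/MS/LS; deviation of
    the target from the vision center on [0, 0.5] with terms SD/MD/LD.
    Output: following distance on the room's [min, max] band with five
    terms VS/S/M/L/VL.  Terms are evenly spaced triangles (the published
    charts print no break points).  The rule table maps faster speed and
    larger deviation monotonically to closer following.
    """

    dist_min: float
    dist_max: float
    speed_max: float = 1.3
    dev_max: float = 0.5
    resolution: int = 201
    # rule[i][j]: output term index (0=VS .. 4=VL) for speed term i (0=SS..2=LS)
    # and deviation term j (0=SD..2=LD); non-increasing along both axes.
    rules: tuple[tuple[int, int, int], ...] = ((4, 3, 2), (3, 2, 1), (2, 1, 0))

    _grid: np.ndarray = field(init=False, repr=False)
    _out_mfs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.dist_min < self.dist_max:
            raise ValueError("need 0 < dist_min < dist_max")
        for row in self.rules:
            if list(row) != sorted(row, reverse=True):
                raise ValueError("rule rows must be non-increasing in deviation")
        for col in zip(*self.rules):
            if list(col) != sorted(col, reverse=True):
                raise ValueError("rule columns must be non-increasing in speed")
        self._grid = np.linspace(self.dist_min, self.dist_max, self.resolution)
        centers = np.linspace(self.dist_min, self.dist_max, 5)
        step = centers[1] - centers[0]
        self._out_mfs = np.stack(
            [_tri(self._grid, c - step, c, c + step) for c in centers]
        )

    @classmethod
    def for_room(cls, room: Room) -> "FuzzyConfig":
        lo, hi = room.follow_bounds
        return cls(dist_min=lo, dist_max=hi)

    def _input_memberships(self, x: float, xmax: float) -> np.ndarray:
        x = float(np.clip(x, 0.0, xmax))
        half = xmax / 2
        return np.array(
            [
                _tri(np.array([x]), 0.0, 0.0, half)[0],
                _tri(np.array([x]), 0.0, half, xmax)[0],
                _tri(np.array([x]), half, xmax, xmax)[0],
            ]
        )

    def desired_distance(self, speed: float, deviation: float) -> float:
        """Mamdani min-max inference with centroid defuzzification."""
        mu_s = self._input_memberships(speed, self.speed_max)
        mu_d = self._input_memberships(deviation, self.dev_max)
        agg = np.zeros_like(self._grid)
        for i in range(3):
            for j in range(3):
                strength = min(mu_s[i], mu_d[j])
                if strength > 0:
                    clipped = np.minimum(self._out_mfs[self.rules[i][j]], strength)
                    agg = np.maximum(agg, clipped)
        total = float(agg.sum())
        if total == 0.0:  # cannot happen on covered universes; guard anyway
            return (self.dist_min + self.dist_max) / 2
        return float((agg * self._grid).sum() / total)


def fuzzy_desired_distance(speed: float, deviation: float, cfg: FuzzyConfig) -> float:
    """Desired following distance (m) for a target speed and deviation."""
    return cfg.desired_distance(speed, deviation)


def algorithm3_step(
    reading: SensorReading,
    estimated_speed: float,
    cfg: FuzzyConfig,
    gains: ControlGains | None = None,
) -> FollowCommand:
    """Servo toward the fuzzy desired distance; stop when undetected.

    ``estimated_speed`` comes from the perception speed estimator and is 0
    until its warm-up window has filled.
    """
    if not reading.visible:
        return STOP
    g = gains or ControlGains()
    desired = cfg.desired_distance(estimated_speed, reading.deviation)
    # hold the fuzzy set-point loosely: idle inside a small deadband so the
    # adaptive follower shares the band follower's economy
    if abs(reading.distance - desired) < 0.25:
        w = float(np.clip(g.kp_bearing * reading.bearing, -g.max_w, g.max_w))
        return FollowCommand(0.0, w)
    return _servo(reading, desired, g)


# ---------------------------------------------------------------------------
# stateful wrappers with the run_scenario follower interface
# ---------------------------------------------------------------------------


class Algorithm1:
    """Fixed-distance follower (stateless)."""

    def __init__(self, target_distance: float, gains: ControlGains | None = None):
        self.target_distance = target_distance
        self.gains = gains or ControlGains()

    @classmethod
    def for_room(cls, room: Room) -> "Algorithm1":
        return cls(sum(room.follow_bounds) / 2)

    def update(self, robot_pose, reading: SensorReading, dt: float) -> FollowCommand:
        return algorithm1_step(reading, self.target_distance, self.gains)


class Algorithm2:
    """Distance-band follower (stateless)."""

    def __init__(self, bounds: tuple[float, float], gains: ControlGains | None = None):
        self.bounds = bounds
        self.gains = gains or ControlGains()

    @classmethod
    def for_room(cls, room: Room) -> "Algorithm2":
        return cls(room.follow_bounds)

    def update(self, robot_pose, reading: SensorReading, dt: float) -> FollowCommand:
        return algorithm2_step(reading, self.bounds, self.gains)


class Algorithm3:
    """Fuzzy adaptive-distance follower.

    Maintains its own target-speed estimate (position triangulated from the
    robot pose and the range/bearing reading, sampled at 1 Hz, 5 s moving
    mean) so it needs no external perception wiring.
    """

    def __init__(self, cfg: FuzzyConfig, gains: ControlGains | None = None):
        self.cfg = cfg
        self.gains = gains or ControlGains()
        self.estimator = TrackEstimator()

    @classmethod
    def for_room(cls, room: Room) -> "Algorithm3":
        return cls(FuzzyConfig.for_room(room))

    def update(self, robot_pose, reading: SensorReading, dt: float) -> FollowCommand:
        self.estimator.update(robot_pose, reading)
        speed = self.estimator.smoothed_speed or 0.0
        return algorithm3_step(reading, speed, self.cfg, self.gains)


def make_follower(algorithm: int, room: Room):
    """Follower instance (1 | 2 | 3) configured for a room fixture."""
    if algorithm == 1:
        return Algorithm1.for_room(room)
    if algorithm == 2:
        return Algorithm2.for_room(room)
    if algorithm == 3:
        return Algorithm3.for_room(room)
    raise ValueError(f"algorithm must be 1, 2 or 3, got {algorithm}")
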