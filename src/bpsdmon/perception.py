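"""Deriving manifestations from simulation: position, speed, wandering.

The robot only measures range and bearing; the target's world position is
triangulated from the robot's own pose, speed is the per-second
displacement of those estimates (with a 5-s moving mean used for
judgement), and wandering is detected by counting in-order traversals of
marker rectangles laid along the room's repetitive-locomotion route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from shapely.geometry import Point, Polygon

from .regularities import DOMAIN_BOUNDS, discretize_speed

__all__ = [
    "estimate_position",
    "TrackEstimator",
    "WanderingDetector",
    "ManifestationRecord",
    "assemble_record",
]


def estimate_position(robot_pose, reading) -> tuple[float, float]:
    """Target world position from the robot pose and a visible reading.

    The sensor ray leaves the robot at (heading + bearing):
    ``XT = XR + d*cos(theta)``, ``YT = YR + d*sin(theta)``.
    """
    if not reading.visible:
        raise ValueError("cannot estimate position from an invisible reading")
    theta = robot_pose.heading + reading.bearing
    return (
        robot_pose.x + reading.distance * math.cos(theta),
        robot_pose.y + reading.distance * math.sin(theta),
    )


class TrackEstimator:
    """Target track from 1-Hz position estimates.

    ``v_inst`` is the Euclidean displacement between consecutive 1-s
    samples (undefined across visibility gaps); ``smoothed_speed`` is the
    mean of the trailing 5 instantaneous values and is None until that
    window has filled.
    """

    def __init__(self, sample_period: float = 1.0, window: int = 5) -> None:
        self.sample_period = sample_period
        self.window = window
        self.positions: list[tuple[float, float, float]] = []  # (t, x, y)
        self.speeds: list[tuple[float, float]] = []  # (t, v)
        self.smoothed: list[tuple[float, float]] = []  # (t, 5-s mean)
        self._last_sample: Optional[tuple[float, float, float]] = None
        self._recent: list[float] = []

    def update(self, robot_pose, reading) -> None:
        """Feed one tick; samples are only taken at the 1-Hz cadence and
        only while the target is visible."""
        if not reading.visible:
            return
        t = reading.t
        if self._last_sample is not None and t - self._last_sample[0] < self.sample_period - 1e-9:
            return
        x, y = estimate_position(robot_pose, reading)
        if self._last_sample is not None:
            gap = t - self._last_sample[0]
            if gap <= 1.5 * self.sample_period:
                v = math.hypot(x - self._last_sample[1], y - self._last_sample[2]) / gap
                self.speeds.append((t, v))
                self._recent.append(v)
                if len(self._recent) > self.window:
                    self._recent.pop(0)
                if len(self._recent) == self.window:
                    self.smoothed.append((t, sum(self._recent) / self.window))
            else:
                self._recent.clear()  # occlusion gap: restart the window
        self._last_sample = (t, x, y)
        self.positions.append((t, x, y))

    @property
    def v_inst(self) -> Optional[float]:
        return self.speeds[-1][1] if self.speeds else None

    @property
    def smoothed_speed(self) -> Optional[float]:
        return self.smoothed[-1][1] if self.smoothed else None

    def mean_smoothed_speed(self) -> Optional[float]:
        """Mean of all 5-s smoothed samples over the run."""
        if not self.smoothed:
            return None
        return sum(v for _, v in self.smoothed) / len(self.smoothed)

    def median_smoothed_speed(self) -> Optional[float]:
        """Median of the smoothed samples: the run-level walking-speed
        judgement.  The median ignores brief rests (e.g. after the person
        sits down) and turn transients that would bias a mean."""
        if not self.smoothed:
            return None
        vals = sorted(v for _, v in self.smoothed)
        mid = len(vals) // 2
        if len(vals) % 2:
            return vals[mid]
        return 0.5 * (vals[mid - 1] + vals[mid])

    def detected_speed_level(self) -> Optional[int]:
        v = self.median_smoothed_speed()
        return None if v is None else discretize_speed(v)

    # run_scenario observer hook
    def observe(self, world, reading) -> None:
        self.update(world.robot, reading)


class WanderingDetector:
    """Order-sensitive rectangle-traversal counter.

    A "circle" is one in-order traversal of all ``n`` marker rectangles
    (4 for a lapping loop, 2 for a pacing segment); wandering is flagged
    after ``threshold`` circles.  Entering a rectangle out of cyclic order
    restarts the sequence at that rectangle and never increments the
    count.
    """

    def __init__(self, rectangles: Sequence[Polygon], threshold: int = 4) -> None:
        if len(rectangles) < 2:
            raise ValueError("need at least two marker rectangles")
        self.rectangles = list(rectangles)
        self.threshold = threshold
        self.circle_count = 0
        self._inside: Optional[int] = None  # rectangle currently occupied
        self._expected: Optional[int] = None
        self._progress = 0

    @property
    def wandering(self) -> bool:
        return self.circle_count >= self.threshold

    def _rect_at(self, point: tuple[float, float]) -> Optional[int]:
        pt = Point(point)
        for i, rect in enumerate(self.rectangles):
            if rect.covers(pt):
                return i
        return None

    def update(self, point: tuple[float, float]) -> bool:
        """Feed one (estimated) target position; returns current flag."""
        here = self._rect_at(point)
        if here is None or here == self._inside:
            self._inside = here if here is not None else None
            return self.wandering
        # entry transition into rectangle `here`
        self._inside = here
        n = len(self.rectangles)
        if self._expected is not None and here != self._expected:
            self._progress = 0  # out of order: restart the sequence here
        self._progress += 1
        self._expected = (here + 1) % n
        if self._progress == n:
            self.circle_count += 1
            self._progress = 0
        return self.wandering

    # run_scenario observer hook: track estimated positions when visible
    def observe(self, world, reading) -> None:
        if reading.visible:
            self.update(estimate_position(world.robot, reading))


_RECORD_DOMAINS = {
    "time": "time6",
    "environmental_change": "ordinal4",
    "walking_speed": "ordinal4",
    "hrv": "ordinal4",
    "daytime_activity": "ordinal4",
    "wandering": "binary",
}


@dataclass(frozen=True)
class ManifestationRecord:
    """The six-feature sensor-side input to the BePhyEn classifiers."""

    time: int
    environmental_change: int
    walking_speed: int
    hrv: int
    daytime_activity: int
    wandering: int

    def __post_init__(self) -> None:
        for name, domain in _RECORD_DOMAINS.items():
            lo, hi = DOMAIN_BOUNDS[domain]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside domain [{lo}, {hi}]")

    def values(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in _RECORD_DOMAINS}


def assemble_record(
    detected_speed_level: Optional[int],
    detected_wandering: bool,
    context: dict,
) -> Optional[ManifestationRecord]:
    """Combine detected manifestations with assumed-known context levels.

    ``context`` supplies time, environmental_change, hrv and
    daytime_activity (levels the platform is assumed to know).  Returns
    None when the target was lost before a speed judgement could be made —
    the experiment then counts the sample as a failure.
    """
    if detected_speed_level is None:
        return None
    return ManifestationRecord(
        time=int(context["time"]),
        environmental_change=int(context["environmental_change"]),
        walking_speed=int(detected_speed_level),
        hrv=int(context["hrv"]),
        daytime_activity=int(context["daytime_activity"]),
        wandering=int(detected_wandering),
    )
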