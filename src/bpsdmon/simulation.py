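"""2D kinematic virtual-home world.

Replaces the original 3D game-engine environment with a flat geometric
one: a room is a boundary polygon with rectangular furniture, the elderly
target is a point following a scripted waypoint route at constant speed,
and the robot is a disc with unicycle kinematics and a range/bearing
sensor limited by field of view, range, and line of sight.

The three packaged room fixtures are authored approximations of the
published rooms (whose exact meshes are not available): room1 is large
with few occlusions, room2 small with more occlusions, room3 is room1
with extra furniture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, box

__all__ = [
    "Pose",
    "Room",
    "TargetScript",
    "SensorReading",
    "SimConfig",
    "World",
    "SimLog",
    "line_of_sight",
    "sense",
    "run_scenario",
    "route_script",
    "wandering_script",
]


def wrap_angle(a: float) -> float:
    """Normalize an angle to (-pi, pi]."""
    a = math.fmod(a, 2 * math.pi)
    if a <= -math.pi:
        a += 2 * math.pi
    elif a > math.pi:
        a -= 2 * math.pi
    return a


@dataclass
class Pose:
    x: float
    y: float
    heading: float = 0.0

    def __post_init__(self) -> None:
        self.heading = wrap_angle(self.heading)

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


class Room:
    """Room geometry plus the monitoring metadata attached to it.

    ``follow_bounds`` is the (min, max) robot-target distance band in
    meters; ``wandering_mode`` ("lapping" or "pacing") selects which
    repetitive-locomotion pattern is scripted and detected in this room,
    with ``wander_rect_centers`` the ordered marker-rectangle centers.
    """

    WANDER_RECT_SIZE = 0.5  # m, side of a marker rectangle

    def __init__(self, payload: dict) -> None:
        self.name: str = payload["name"]
        self.boundary = Polygon(payload["boundary"])
        self.furniture: list[Polygon] = []
        self.furniture_names: list[str] = []
        for f in payload.get("furniture", []):
            x0, y0, x1, y1 = f["rect"]
            self.furniture.append(box(x0, y0, x1, y1))
            self.furniture_names.append(f.get("name", "furniture"))
        self.places: dict[str, tuple[float, float]] = {
            k: tuple(v) for k, v in payload.get("places", {}).items()
        }
        self.roadmap: list[tuple[float, float]] = [tuple(p) for p in payload["roadmap"]]
        self.follow_bounds: tuple[float, float] = tuple(payload["follow_bounds"])
        wandering = payload.get("wandering", {})
        self.wandering_mode: str = wandering.get("mode", "lapping")
        self.wander_rect_centers: list[tuple[float, float]] = [
            tuple(c) for c in wandering.get("rect_centers", [])
        ]
        self.wandering_route: list[tuple[float, float]] = [
            tuple(p) for p in payload.get("wandering_route", [])
        ]
        for geom in (self.boundary, *self.furniture):
            shapely.prepare(geom)
        self._validate()

    def _validate(self) -> None:
        lo, hi = self.follow_bounds
        if not 0 < lo < hi:
            raise ValueError(f"bad follow bounds {self.follow_bounds}")
        for furn in self.furniture:
            if not self.boundary.contains(furn):
                raise ValueError(f"furniture outside boundary in {self.name}")
        for p in self.roadmap + self.wandering_route:
            if not self.free(p):
                raise ValueError(f"waypoint {p} not in free space of {self.name}")

    @classmethod
    def load(cls, name: str) -> "Room":
        """Load a packaged fixture ("room1" | "room2" | "room3") or a path."""
        if name in ("room1", "room2", "room3"):
            ref = resources.files("bpsdmon.data.rooms") / f"{name}.json"
            payload = json.loads(ref.read_text())
        else:
            with open(name) as fh:
                payload = json.load(fh)
        return cls(payload)

    def free(self, p: tuple[float, float], radius: float = 0.0) -> bool:
        """Point (or disc of given radius) lies inside the walls and clear
        of furniture."""
        pt = Point(p)
        if radius <= 0:
            if not self.boundary.covers(pt):
                return False
            return not any(f.covers(pt) for f in self.furniture)
        if not self.boundary.covers(pt) or self.boundary.exterior.distance(pt) < radius:
            return False
        return all(f.distance(pt) >= radius for f in self.furniture)

    def wander_rects(self) -> list[Polygon]:
        h = self.WANDER_RECT_SIZE / 2
        return [box(cx - h, cy - h, cx + h, cy + h) for cx, cy in self.wander_rect_centers]


def line_of_sight(room: Room, p, q) -> bool:
    """True iff the open segment pq stays inside the walls and touches no
    furniture.  A segment that merely grazes a furniture edge counts as
    blocked (conservative visibility)."""
    p = p.xy if isinstance(p, Pose) else tuple(p)
    q = q.xy if isinstance(q, Pose) else tuple(q)
    seg = LineString([p, q])
    if not room.boundary.covers(seg):
        return False
    return not any(f.intersects(seg) for f in room.furniture)


@dataclass(frozen=True)
class SensorReading:
    """One range/bearing measurement; invalid unless ``visible``."""

    visible: bool
    distance: float
    bearing: float  # rad, 0 = vision center, positive = target to the left
    t: float

    @property
    def deviation(self) -> float:
        """|bearing| mapped onto the controller's 0-0.5 deviation universe
        (0.5 = at the edge of the field of view)."""
        return min(abs(self.bearing) / (SimConfig.fov / 2) * 0.5, 0.5)


@dataclass
class SimConfig:
    """Simulator constants; defaults documented in the methods note."""

    dt: float = 0.1  # s
    robot_radius: float = 0.25  # m
    person_radius: float = 0.2  # m
    max_v: float = 1.5  # m/s
    max_w: float = 2.0  # rad/s
    max_range: float = 5.0  # m
    lost_threshold: float = 3.0  # s of continuous invisibility
    noise_distance_std: float = 0.0  # m, optional Gaussian sensor noise
    noise_bearing_std: float = 0.0  # rad
    seed: int = 0

    fov = math.pi / 2  # rad, full field of view (class constant)


class TargetScript:
    """Constant-speed motion along a waypoint polyline.

    Behaviors: ``route`` stops and holds at the last waypoint; ``lapping``
    cycles a closed loop; ``pacing`` shuttles back and forth along the
    polyline.  ``max_travel`` (m) optionally ends lapping/pacing motion
    after a given path length.
    """

    def __init__(
        self,
        route: Iterable[tuple[float, float]],
        speed: float,
        behavior: str = "route",
        max_travel: Optional[float] = None,
    ) -> None:
        pts = [tuple(p) for p in route]
        if len(pts) < 2:
            raise ValueError("a script needs at least two waypoints")
        if speed <= 0:
            raise ValueError("target speed must be positive")
        if behavior not in ("route", "lapping", "pacing"):
            raise ValueError(f"unknown behavior {behavior!r}")
        if behavior == "lapping" and pts[0] != pts[-1]:
            pts = pts + [pts[0]]
        self.points = np.array(pts, dtype=float)
        seg = np.diff(self.points, axis=0)
        self.seg_len = np.hypot(seg[:, 0], seg[:, 1])
        self.cum = np.concatenate([[0.0], np.cumsum(self.seg_len)])
        self.length = float(self.cum[-1])
        self.speed = float(speed)
        self.behavior = behavior
        self.max_travel = max_travel

    def _arc_to_point(self, s: float) -> tuple[float, float]:
        s = min(max(s, 0.0), self.length)
        i = int(np.searchsorted(self.cum, s, side="right")) - 1
        i = min(i, len(self.seg_len) - 1)
        frac = (s - self.cum[i]) / self.seg_len[i] if self.seg_len[i] > 0 else 0.0
        p = self.points[i] + frac * (self.points[i + 1] - self.points[i])
        return (float(p[0]), float(p[1]))

    def position(self, travelled: float) -> tuple[float, float]:
        """Position after the target has walked ``travelled`` meters."""
        if self.max_travel is not None:
            travelled = min(travelled, self.max_travel)
        if self.behavior == "route":
            return self._arc_to_point(travelled)
        if self.behavior == "lapping":
            return self._arc_to_point(travelled % self.length)
        # pacing: triangle-wave reflection
        period = 2 * self.length
        s = travelled % period
        return self._arc_to_point(s if s <= self.length else period - s)

    def done(self, travelled: float) -> bool:
        if self.behavior == "route":
            return travelled >= self.length
        return self.max_travel is not None and travelled >= self.max_travel


def chamfer_route(
    points: list[tuple[float, float]], cut: float = 0.45, closed: bool = False
) -> list[tuple[float, float]]:
    """Round polyline corners by replacing each interior vertex with two
    points ``cut`` meters along its adjacent segments (people round
    corners; a hard 90-degree vertex would make the per-second
    displacement-based speed estimate undershoot at every turn)."""
    pts = [np.asarray(p, dtype=float) for p in points]
    if closed and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = len(pts)
    out: list[tuple[float, float]] = []
    idx = range(n) if closed else range(1, n - 1)
    if not closed:
        out.append(tuple(pts[0]))
    for i in idx:
        prev_, cur, next_ = pts[(i - 1) % n], pts[i], pts[(i + 1) % n]
        for other in (prev_, next_):
            d = other - cur
            L = float(np.hypot(*d))
            c = min(cut, L / 2.5)
            out.append(tuple(cur + (c / L) * d if L > 0 else cur))
    if not closed:
        out.append(tuple(pts[-1]))
    return out


def route_script(room: Room, speed: float) -> TargetScript:
    """The daily-living scenario: enter, eat in the dining room, watch TV
    in the living room, rest in the bedroom — the room's fixed roadmap
    (corners rounded)."""
    return TargetScript(chamfer_route(room.roadmap), speed, "route")


def wandering_script(room: Room, speed: float, cycles: float | None = None) -> TargetScript:
    """Scripted wandering in this room's mode.

    ``cycles``: number of loop laps (lapping) or one-way traversals
    (pacing) to walk before stopping.  Defaults (5 laps / 10 traversals)
    give the detector its four full in-order circles with margin.
    """
    route = room.wandering_route
    if not route:
        raise ValueError(f"{room.name} has no wandering route")
    if cycles is None:
        cycles = 5.0 if room.wandering_mode == "lapping" else 10.0
    if room.wandering_mode == "lapping":
        # small cut so the rounded path still crosses the corner marker
        # rectangles used by the wandering detector
        route = chamfer_route(route, cut=0.3, closed=True)
    script = TargetScript(
        route, speed, room.wandering_mode,
    )
    script.max_travel = cycles * script.length
    return script


@dataclass
class TickRecord:
    t: float
    target: tuple[float, float]
    robot: tuple[float, float, float]
    reading: SensorReading
    command: tuple[float, float]
    lost_event: bool = False
    collision_event: bool = False


@dataclass
class SimLog:
    """Full per-tick trace of one scenario run."""

    room: str
    ticks: list[TickRecord] = field(default_factory=list)
    robot_distance: float = 0.0
    target_distance: float = 0.0
    lost_count: int = 0
    collision_count: int = 0

    def final_invisible_duration(self) -> float:
        """Length (s) of the trailing stretch with the target undetected;
        0 if the run ended while tracking."""
        if not self.ticks:
            return 0.0
        t_end = self.ticks[-1].t
        for r in reversed(self.ticks):
            if r.reading.visible:
                return t_end - r.t
        return t_end - self.ticks[0].t

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.ticks:
                fh.write(json.dumps({
                    "t": round(r.t, 3),
                    "target": [round(v, 4) for v in r.target],
                    "robot": [round(v, 4) for v in r.robot],
                    "visible": r.reading.visible,
                    "distance": round(r.reading.distance, 4),
                    "bearing": round(r.reading.bearing, 4),
                    "command": [round(v, 4) for v in r.command],
                    "lost": r.lost_event,
                    "collision": r.collision_event,
                }) + "\n")


class World:
    """Mutable per-tick state: target arc position, robot pose, odometers."""

    def __init__(self, room: Room, script: TargetScript, cfg: SimConfig) -> None:
        self.room = room
        self.script = script
        self.cfg = cfg
        self.t = 0.0
        self.travelled = 0.0
        self.target = script.position(0.0)
        self.robot = self._initial_robot_pose()
        self.robot_distance = 0.0
        self.target_distance = 0.0
        self.rng = np.random.default_rng(cfg.seed)
        self.in_collision = False

    def _initial_robot_pose(self) -> Pose:
        """Start the robot at mid-band distance behind the target, facing
        it.  If the spot directly behind the first route segment is not
        free (or has no line of sight), candidate positions are tried at
        increasing angular offsets and then at shorter gaps."""
        p0 = np.array(self.script.position(0.0))
        p1 = np.array(self.script.position(min(0.5, self.script.length)))
        d = p1 - p0
        norm = float(np.hypot(*d))
        base = math.atan2(d[1], d[0]) + math.pi if norm > 0 else 0.0
        mid_gap = sum(self.room.follow_bounds) / 2
        for off in (0.0, 0.5, -0.5, 1.0, -1.0, 1.6, -1.6, 2.4, -2.4, math.pi):
            for gap in (mid_gap, self.room.follow_bounds[0], 0.8, 0.5):
                pos = p0 + gap * np.array([math.cos(base + off), math.sin(base + off)])
                if self.room.free(tuple(pos), self.cfg.robot_radius) and line_of_sight(
                    self.room, tuple(pos), tuple(p0)
                ):
                    heading = math.atan2(p0[1] - pos[1], p0[0] - pos[0])
                    return Pose(float(pos[0]), float(pos[1]), heading)
        raise ValueError(f"no free robot start position in {self.room.name}")

    def _robot_move_ok(self, old: tuple[float, float], new: tuple[float, float]) -> bool:
        r = self.cfg.robot_radius
        if not self.room.free(new, r):
            return False
        seg = LineString([old, new])
        if seg.length > 0 and any(f.distance(seg) < r for f in self.room.furniture):
            return False
        return True

    def step(self, command: tuple[float, float], dt: float) -> None:
        """Advance one tick: target along its script, robot by unicycle
        kinematics with commands clamped to limits; a move that would put
        the robot disc into a wall or furniture is refused at contact and
        logged as a collision."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        cfg = self.cfg
        v = float(np.clip(command[0], -cfg.max_v, cfg.max_v))
        w = float(np.clip(command[1], -cfg.max_w, cfg.max_w))

        # target: distance accumulates along the walked path (arc length),
        # capped where the script stops moving
        prev = self.travelled
        if not self.script.done(self.travelled):
            self.travelled += self.script.speed * dt
        cap = self.script.max_travel
        if self.script.behavior == "route":
            cap = self.script.length if cap is None else min(cap, self.script.length)
        walked_prev = prev if cap is None else min(prev, cap)
        walked_now = self.travelled if cap is None else min(self.travelled, cap)
        self.target_distance += walked_now - walked_prev
        self.target = self.script.position(self.travelled)

        # robot
        heading = wrap_angle(self.robot.heading + w * dt)
        nx = self.robot.x + v * dt * math.cos(heading)
        ny = self.robot.y + v * dt * math.sin(heading)
        collided = False
        if self._robot_move_ok(self.robot.xy, (nx, ny)):
            self.robot_distance += math.hypot(nx - self.robot.x, ny - self.robot.y)
            self.robot = Pose(nx, ny, heading)
        else:
            collided = abs(v) > 1e-9
            self.robot = Pose(self.robot.x, self.robot.y, heading)
        # bumping into the person also counts as a collision
        if (
            math.hypot(self.target[0] - self.robot.x, self.target[1] - self.robot.y)
            < cfg.robot_radius + cfg.person_radius
        ):
            collided = True
        self.in_collision = collided
        self.t += dt


def sense(world: World) -> SensorReading:
    """Range/bearing measurement of the target from the robot.

    Visible iff the target is within sensor range, within the (closed)
    field-of-view cone, and in line of sight.  Optional zero-mean Gaussian
    noise on distance and bearing is applied after the visibility test.
    """
    cfg = world.cfg
    dx = world.target[0] - world.robot.x
    dy = world.target[1] - world.robot.y
    dist = math.hypot(dx, dy)
    bearing = wrap_angle(math.atan2(dy, dx) - world.robot.heading)
    visible = (
        dist <= cfg.max_range
        and abs(bearing) <= cfg.fov / 2
        and line_of_sight(world.room, world.robot.xy, world.target)
    )
    if visible and (cfg.noise_distance_std > 0 or cfg.noise_bearing_std > 0):
        dist = max(0.0, dist + float(world.rng.normal(0, cfg.noise_distance_std)))
        bearing = wrap_angle(bearing + float(world.rng.normal(0, cfg.noise_bearing_std)))
    if not visible:
        return SensorReading(False, float("nan"), float("nan"), world.t)
    return SensorReading(True, dist, bearing, world.t)


def run_scenario(
    room: Room,
    follower,
    script: TargetScript,
    duration: float,
    cfg: SimConfig | None = None,
    observers: Iterable = (),
) -> SimLog:
    """Run one following scenario and return the full log.

    ``follower`` implements ``update(robot_pose, reading, dt) ->
    FollowCommand``; ``observers`` get ``observe(world, reading)`` each
    tick (perception pipelines hook in here).  With sensor noise off the
    run is exactly deterministic.  The run ends at ``duration`` or two
    The run ends at ``duration`` or six
    seconds after a ``route`` script reaches its final waypoint (time for
    the follower to settle and re-acquire after a terminal occlusion).
    """
    cfg = cfg or SimConfig()
    world = World(room, script, cfg)
    log = SimLog(room=room.name)
    invisible_since: float | None = None
    lost_flagged = False
    was_colliding = False
    end_grace: float | None = None

    t = 0.0
    while t < duration:
        reading = sense(world)
        for obs in observers:
            obs.observe(world, reading)
        if reading.visible:
            invisible_since = None
            lost_flagged = False
        else:
            if invisible_since is None:
                invisible_since = world.t
        lost_event = False
        if (
            invisible_since is not None
            and not lost_flagged
            and world.t - invisible_since >= cfg.lost_threshold
        ):
            lost_event = True
            lost_flagged = True
            log.lost_count += 1

        command = follower.update(world.robot, reading, cfg.dt)
        world.step((command.v, command.w), cfg.dt)

        collision_event = world.in_collision and not was_colliding
        if collision_event:
            log.collision_count += 1
        was_colliding = world.in_collision

        log.ticks.append(
            TickRecord(
                t=world.t,
                target=world.target,
                robot=(world.robot.x, world.robot.y, world.robot.heading),
                reading=reading,
                command=(command.v, command.w),
                lost_event=lost_event,
                collision_event=collision_event,
            )
        )
        t = world.t
        if world.script.done(world.travelled):
            if end_grace is None:
                end_grace = t + 6.0
            elif t >= end_grace:
                break
    log.robot_distance = world.robot_distance
    log.target_distance = world.target_distance
    return log
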