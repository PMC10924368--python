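"""World geometry, kinematics, sensing, and scenario determinism."""

import json
import math
from fractions import Fraction

import numpy as np
import pytest

from bpsdmon.following import make_follower
from bpsdmon.simulation import (
    Pose,
    Room,
    SimConfig,
    TargetScript,
    World,
    line_of_sight,
    route_script,
    run_scenario,
    sense,
    wandering_script,
    wrap_angle,
)


def _empty_room(w=8.0, h=6.0):
    return Room(
        {
            "name": "empty",
            "boundary": [[0, 0], [w, 0], [w, h], [0, h]],
            "furniture": [],
            "roadmap": [[1, 1], [w - 1, 1]],
            "follow_bounds": [1.3, 2.1],
        }
    )


def _room_with_box():
    return Room(
        {
            "name": "boxroom",
            "boundary": [[0, 0], [8, 0], [8, 6], [0, 6]],
            "furniture": [{"name": "box", "rect": [3, 2, 5, 4]}],
            "roadmap": [[1, 1], [7, 1]],
            "follow_bounds": [1.3, 2.1],
        }
    )


# ---------------------------------------------------------------------------
# line of sight
# ---------------------------------------------------------------------------


def test_line_of_sight_clear_in_empty_room():
    room = _empty_room()
    assert line_of_sight(room, (1, 1), (7, 5))


def test_line_of_sight_blocked_by_furniture():
    room = _room_with_box()
    assert not line_of_sight(room, (1, 3), (7, 3))  # crosses the box
    assert line_of_sight(room, (1, 1), (7, 1))  # passes south of it


def test_grazing_touch_counts_as_blocked():
    room = _room_with_box()
    # segment touching the box's bottom edge y=2
    assert not line_of_sight(room, (1, 2), (7, 2))
    # endpoint exactly on a corner
    assert not line_of_sight(room, (1, 1), (3, 2))


def _exact_segment_blocked(p, q, rect):
    """Exact rational-arithmetic oracle: does segment pq touch the closed
    axis-aligned rectangle?  Uses Liang-Barsky clipping with Fractions."""
    (x0, y0), (x1, y1) = p, q
    x0, y0, x1, y1 = map(Fraction, (x0, y0, x1, y1))
    xmin, ymin, xmax, ymax = map(Fraction, rect)
    t0, t1 = Fraction(0), Fraction(1)
    dx, dy = x1 - x0, y1 - y0
    for pd, qd in (
        (-dx, x0 - xmin),
        (dx, xmax - x0),
        (-dy, y0 - ymin),
        (dy, ymax - y0),
    ):
        if pd == 0:
            if qd < 0:
                return False
        else:
            r = qd / pd
            if pd < 0:
                if r > t1:
                    return False
                t0 = max(t0, r)
            else:
                if r < t0:
                    return False
                t1 = min(t1, r)
    return t0 <= t1


def test_line_of_sight_matches_exact_rational_oracle():
    room = _room_with_box()
    rect = (3, 2, 5, 4)
    rng = np.random.default_rng(0)
    agree = 0
    for _ in range(300):
        # quarter-unit grid points keep float geometry exact
        p = tuple(rng.integers(2, 31, 2) / 4)
        q = tuple(rng.integers(2, 31, 2) / 4)
        if p == q or not (room.free(p) and room.free(q)):
            continue
        blocked = not line_of_sight(room, p, q)
        assert blocked == _exact_segment_blocked(p, q, rect)
        agree += 1
    assert agree > 100  # the comparison actually exercised many cases


# ---------------------------------------------------------------------------
# scripts and stepping
# ---------------------------------------------------------------------------


def test_wrap_angle():
    assert wrap_angle(3 * math.pi) == pytest.approx(math.pi)
    assert wrap_angle(-math.pi) == pytest.approx(math.pi)
    assert wrap_angle(0.5) == pytest.approx(0.5)


def test_target_script_behaviors():
    route = TargetScript([(0, 0), (4, 0)], speed=1.0, behavior="route")
    assert route.position(2.0) == pytest.approx((2, 0))
    assert route.position(99.0) == pytest.approx((4, 0))  # holds at the end
    assert route.done(4.0)

    lap = TargetScript([(0, 0), (2, 0), (2, 2), (0, 2)], 1.0, "lapping")
    assert lap.length == pytest.approx(8.0)
    assert lap.position(8.0) == pytest.approx((0, 0))
    assert lap.position(9.0) == pytest.approx((1, 0))

    pace = TargetScript([(0, 0), (3, 0)], 1.0, "pacing")
    assert pace.position(4.0) == pytest.approx((2, 0))  # reflected
    assert pace.position(6.0) == pytest.approx((0, 0))


def test_step_world_zero_command_and_target_advance():
    room = _empty_room()
    script = TargetScript([(1, 1), (7, 1)], speed=1.0)
    world = World(room, script, SimConfig())
    robot_before = world.robot.xy
    world.step((0.0, 0.0), 0.5)
    assert world.robot.xy == robot_before
    assert world.target == pytest.approx((1.5, 1))
    assert world.target_distance == pytest.approx(0.5)
    with pytest.raises(ValueError):
        world.step((0, 0), 0.0)


def test_commanded_into_wall_is_refused_and_logged():
    room = _empty_room()
    script = TargetScript([(1, 1), (7, 1)], speed=0.0001)
    world = World(room, script, SimConfig())
    world.robot = Pose(0.5, 3.0, math.pi)  # facing the west wall
    for _ in range(20):
        world.step((1.0, 0.0), 0.1)
    assert world.robot.x >= room.boundary.bounds[0] + world.cfg.robot_radius - 1e-9
    assert world.in_collision


def test_sense_geometry_and_occlusion():
    room = _room_with_box()
    script = TargetScript([(1, 1), (7, 1)], speed=1.0)
    world = World(room, script, SimConfig())
    world.robot = Pose(1, 1, 0.0)
    world.target = (3, 1)
    r = sense(world)
    assert r.visible and r.distance == pytest.approx(2.0)
    assert r.bearing == pytest.approx(0.0)
    assert r.deviation == pytest.approx(0.0)

    world.target = (7, 3.5)  # behind the box from (1,1)? -> check both
    world.robot = Pose(1, 3, 0.0)
    world.target = (7, 3)
    assert not sense(world).visible  # box blocks

    # out of field of view: target behind the robot
    world.robot = Pose(4, 1, 0.0)
    world.target = (2, 1)
    assert not sense(world).visible

    # beyond sensor range
    room2 = _empty_room(12, 4)
    world2 = World(room2, TargetScript([(1, 1), (11, 1)], 1.0), SimConfig())
    world2.robot = Pose(1, 2, 0.0)
    world2.target = (10.9, 2)
    assert not sense(world2).visible


def test_fov_boundary_is_closed():
    cfg = SimConfig()
    room = _empty_room()
    world = World(room, TargetScript([(1, 1), (7, 1)], 1.0), cfg)
    world.robot = Pose(4, 3, 0.0)
    half = cfg.fov / 2
    d = 1.0
    world.target = (4 + d * math.cos(half), 3 + d * math.sin(half))
    assert sense(world).visible  # exactly on the cone edge counts
    eps = 1e-3
    world.target = (4 + d * math.cos(half + eps), 3 + d * math.sin(half + eps))
    assert not sense(world).visible


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def test_zero_duration_gives_empty_log(rooms):
    room = rooms["room1"]
    log = run_scenario(room, make_follower(1, room), route_script(room, 1.0), 0.0)
    assert log.ticks == [] and log.robot_distance == 0.0


def test_scenario_is_deterministic(rooms):
    room = rooms["room2"]

    def run():
        return run_scenario(
            room, make_follower(3, room), route_script(room, 0.94), 40.0, SimConfig()
        )

    a, b = run(), run()
    assert len(a.ticks) == len(b.ticks)
    assert a.robot_distance == b.robot_distance
    for ra, rb in zip(a.ticks, b.ticks):
        assert ra.robot == rb.robot and ra.target == rb.target


def test_target_distance_conservation(rooms):
    """Noise off: target cumulative distance = speed x moving time."""
    room = rooms["room1"]
    speed = 0.87
    script = route_script(room, speed)
    log = run_scenario(room, make_follower(1, room), script, 10.0, SimConfig())
    assert log.target_distance == pytest.approx(speed * log.ticks[-1].t, rel=1e-9)


def test_route_completes_with_path_length(rooms):
    room = rooms["room1"]
    speed = 1.0
    script = route_script(room, speed)
    log = run_scenario(
        room, make_follower(3, room), script, script.length / speed + 25, SimConfig()
    )
    assert log.target_distance == pytest.approx(script.length, abs=0.2)
    assert log.ticks[-1].target == pytest.approx(tuple(script.points[-1]), abs=1e-6)


def test_robot_never_exits_room(rooms):
    for name, room in rooms.items():
        script = route_script(room, 1.2)
        log = run_scenario(
            room, make_follower(2, room), script, script.length / 1.2 + 10, SimConfig()
        )
        r = SimConfig.robot_radius
        for tick in log.ticks[:: 17]:
            assert room.free((tick.robot[0], tick.robot[1]), r * 0.99), (name, tick.t)


def test_jsonl_export(tmp_path, rooms):
    room = rooms["room1"]
    log = run_scenario(room, make_follower(1, room), route_script(room, 1.0), 5.0)
    path = tmp_path / "log.jsonl"
    log.to_jsonl(path)
    lines = path.read_text().splitlines()
    assert len(lines) == len(log.ticks)
    rec = json.loads(lines[0])
    assert set(rec) >= {"t", "target", "robot", "visible", "command"}


def test_wandering_script_lengths(rooms):
    lap = wandering_script(rooms["room1"], 1.0)
    assert lap.behavior == "lapping"
    assert lap.max_travel == pytest.approx(5 * lap.length)
    pace = wandering_script(rooms["room2"], 1.0)
    assert pace.behavior == "pacing"
    assert pace.max_travel == pytest.approx(10 * pace.length)
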