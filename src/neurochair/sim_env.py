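"""2D omnidirectional wheelchair simulation: holonomic kinematics with the
0.1-0.4 m/s speed limits, footprint collision checking, and occupancy-grid
path planning.

The planner rasterises the static obstacles onto a 5 cm grid inflated by the
footprint half-width (0.35 m for the 70 cm chassis) and runs A* with
8-connectivity.  That inscribed-radius inflation is what makes an 80 cm
doorway feasible for a 70 cm chassis - 5 cm of margin per side - provided
the chassis travels aligned with the path, which the holonomic base can
always do.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import rot2d, wrap_angle
from .world import World

V_MIN = 0.1   # m/s
V_MAX = 0.4   # m/s
OMEGA_MAX = 0.6  # rad/s (chassis spec, not printed; modest in-place rate)
GRID_RESOLUTION = 0.05  # m
FOOTPRINT_WIDTH = 0.70  # m
FOOTPRINT_LENGTH = 1.20  # m
CONTROL_DT = 0.1  # s; the control stack runs at 10 Hz


class PathPlanningError(RuntimeError):
    """No collision-free path exists on the inflated grid (NV downstream)."""


@dataclass
class WheelchairState:
    pose: np.ndarray = field(default_factory=lambda: np.zeros(3))  # x, y, theta
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # vx, vy, omega
    width: float = FOOTPRINT_WIDTH
    length: float = FOOTPRINT_LENGTH

    def __post_init__(self) -> None:
        self.pose = np.asarray(self.pose, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)

    def footprint(self, pose=None) -> Polygon:
        pose = self.pose if pose is None else np.asarray(pose, dtype=float)
        half = np.array([[self.length / 2, self.width / 2],
                         [self.length / 2, -self.width / 2],
                         [-self.length / 2, -self.width / 2],
                         [-self.length / 2, self.width / 2]])
        pts = half @ rot2d(pose[2]).T + pose[:2]
        return Polygon(pts)


def clamp_command(cmd) -> np.ndarray:
    """Clamp a body-frame (vx, vy, omega) command to the velocity envelope.

    A non-zero planar speed is clamped into [0.1, 0.4] m/s; zero stays zero.
    """
    vx, vy, om = (float(c) for c in cmd)
    speed = float(np.hypot(vx, vy))
    if speed > 0:
        clamped = float(np.clip(speed, V_MIN, V_MAX))
        vx, vy = vx * clamped / speed, vy * clamped / speed
    om = float(np.clip(om, -OMEGA_MAX, OMEGA_MAX))
    return np.array([vx, vy, om])


def _collides(world: World, footprint: Polygon) -> bool:
    return any(footprint.intersects(ob) for ob in world.obstacles)


def sim_step(world: World, state: WheelchairState, command, dt: float = CONTROL_DT):
    """Advance the world and wheelchair one control step.

    Returns ``(state, events)``; a footprint-obstacle intersection halts the
    motion at the contact point and emits a ``collision`` event.  Agents
    advance by their own velocities.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cmd = clamp_command(command)
    world.advance_agents(dt)
    disp_w = rot2d(state.pose[2]) @ cmd[:2] * dt
    new_pose = state.pose + np.array([disp_w[0], disp_w[1], cmd[2] * dt])
    new_pose[2] = wrap_angle(new_pose[2])
    events: list[dict] = []
    if _collides(world, state.footprint(new_pose)):
        # bisect along the motion to stop just before contact
        lo, hi = 0.0, 1.0
        for _ in range(20):
            mid = (lo + hi) / 2
            trial = state.pose + mid * (new_pose - state.pose)
            if _collides(world, state.footprint(trial)):
                hi = mid
            else:
                lo = mid
        new_pose = state.pose + lo * (new_pose - state.pose)
        events.append({"type": "collision"})
        state.velocity = np.zeros(3)
    else:
        state.velocity = cmd
    state.pose = new_pose
    return state, events


def _occupancy(world: World, inflation: float, resolution: float):
    x0, y0, x1, y1 = world.bounds
    nx = int(np.ceil((x1 - x0) / resolution)) + 1
    ny = int(np.ceil((y1 - y0) / resolution)) + 1
    xs = x0 + np.arange(nx) * resolution
    ys = y0 + np.arange(ny) * resolution
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    occ = np.zeros((nx, ny), dtype=bool)
    if world.obstacles:
        blocked = unary_union(world.obstacles).buffer(inflation)
        occ = shapely.contains_xy(blocked, XX.ravel(), YY.ravel()).reshape(nx, ny)
        occ |= shapely.intersects_xy(blocked.boundary, XX.ravel(),
                                     YY.ravel()).reshape(nx, ny)
    return occ, (x0, y0), resolution


_NEIGHBOURS = [(1, 0, 1.0), (-1, 0, 1.0), (0, 1, 1.0), (0, -1, 1.0),
               (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2)),
               (-1, 1, np.sqrt(2)), (-1, -1, np.sqrt(2))]


def plan_path(
    world: World,
    start_xy,
    goal_xy,
    footprint_width: float = FOOTPRINT_WIDTH,
    resolution: float = GRID_RESOLUTION,
) -> np.ndarray:
    """Shortest grid path for the inflated holonomic footprint.

    Returns an (M, 2) array of waypoints from start to goal.  Raises
    :class:`PathPlanningError` when start or goal is blocked or no path
    exists.
    """
    occ, (ox, oy), res = _occupancy(world, footprint_width / 2, resolution)
    nx, ny = occ.shape

    def to_cell(p):
        i = int(round((p[0] - ox) / res))
        j = int(round((p[1] - oy) / res))
        if not (0 <= i < nx and 0 <= j < ny):
            raise PathPlanningError(f"point {tuple(p)} outside world bounds")
        return i, j

    start = to_cell(start_xy)
    goal = to_cell(goal_xy)
    if occ[start]:
        raise PathPlanningError("start pose is in collision on the inflated grid")
    if occ[goal]:
        raise PathPlanningError("goal pose is in collision on the inflated grid")

    def h(c):
        dx, dy = abs(c[0] - goal[0]), abs(c[1] - goal[1])
        return max(dx, dy) + (np.sqrt(2) - 1) * min(dx, dy)

    g = {start: 0.0}
    came: dict = {}
    pq = [(h(start), start)]
    closed = set()
    while pq:
        _, cur = heapq.heappop(pq)
        if cur == goal:
            break
        if cur in closed:
            continue
        closed.add(cur)
        for di, dj, w in _NEIGHBOURS:
            nb = (cur[0] + di, cur[1] + dj)
            if not (0 <= nb[0] < nx and 0 <= nb[1] < ny) or occ[nb]:
                continue
            cand = g[cur] + w
            if cand < g.get(nb, np.inf):
                g[nb] = cand
                came[nb] = cur
                heapq.heappush(pq, (cand + h(nb), nb))
    else:
        raise PathPlanningError("no collision-free path exists")
    if goal not in g:
        raise PathPlanningError("no collision-free path exists")

    cells = [goal]
    while cells[-1] != start:
        cells.append(came[cells[-1]])
    cells.reverse()
    path = np.array([[ox + i * res, oy + j * res] for i, j in cells])
    path[0] = np.asarray(start_xy, dtype=float)
    path[-1] = np.asarray(goal_xy, dtype=float)
    return path


def path_length(path: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
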