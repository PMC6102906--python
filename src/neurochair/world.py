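"""World model shared by the perception simulator and the 2D session
simulator: static obstacle polygons, doorways, and typed objects/agents."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, Point

#: The ten recognizable object classes.
CLASSES = (
    "person", "chair", "sofa", "bed", "closed_door", "opened_door",
    "desk", "electric_switch", "bottle", "cup",
)


@dataclass
class WorldObject:
    """A detectable object or agent.

    Footprint is either a cylinder (``radius``) or an axis-aligned-in-local-
    frame box (``extent`` = (width, depth), rotated by ``theta``).  ``height``
    is the top of the object above the floor; ``z_base`` the bottom (e.g. a
    bottle standing on a desk has z_base == desk height).
    """

    object_id: int
    cls: str
    position: np.ndarray  # world (x, y)
    height: float
    theta: float = 0.0
    radius: float | None = None
    extent: tuple[float, float] | None = None
    z_base: float = 0.0
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown object class {self.cls!r}")
        if (self.radius is None) == (self.extent is None):
            raise ValueError("exactly one of radius/extent must be set")
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


@dataclass(frozen=True)
class Doorway:
    centre: tuple[float, float]
    width: float
    normal: tuple[float, float]  # unit vector through the doorway

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("doorway width must be positive")


@dataclass
class World:
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    obstacles: list[Polygon] = field(default_factory=list)
    doorways: list[Doorway] = field(default_factory=list)
    agents: list[WorldObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        for poly in self.obstacles:
            if not poly.is_valid or poly.is_empty:
                raise ValueError("obstacles must be valid simple polygons")

    def object_by_id(self, object_id: int) -> WorldObject:
        for a in self.agents:
            if a.object_id == object_id:
                return a
        raise KeyError(f"no object with id {object_id}")

    def advance_agents(self, dt: float) -> None:
        for a in self.agents:
            a.position = a.position + a.velocity * dt


def box_obstacle(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def wall_with_door(x0, y0, x1, y1, door_centre, door_width) -> list[Polygon]:
    """Split an axis-aligned wall rectangle by a door gap.

    The wall must be axis-aligned; ``door_centre`` is the coordinate of the
    gap centre along the wall's long axis.
    """
    horizontal = abs(x1 - x0) >= abs(y1 - y0)
    lo, hi = door_centre - door_width / 2, door_centre + door_width / 2
    parts = []
    if horizontal:
        if lo > x0:
            parts.append(box_obstacle(x0, y0, lo, y1))
        if hi < x1:
            parts.append(box_obstacle(hi, y0, x1, y1))
    else:
        if lo > y0:
            parts.append(box_obstacle(x0, y0, x1, lo))
        if hi < y1:
            parts.append(box_obstacle(x0, hi, x1, y1))
    return parts
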