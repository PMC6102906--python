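"""Built-in test scenarios.

Scenario A reconstructs the hospital-sickroom layout: a room with a desk
carrying bottles of water, an opened door to a long gallery, and a person in
the gallery who walks away when approached.  Scenario B is a slightly more
cluttered two-room variant.  The room dimensions are plausible
reconstructions, not measurements; what matters to the control stack is the
task structure (Table-style step lists), the 80 cm doorway and the dynamic
person.
"""

from __future__ import annotations

import numpy as np

from .session import Scenario, TaskStep
from .world import Doorway, World, WorldObject, box_obstacle, wall_with_door

DOOR_WIDTH = 0.80
WALL = 0.10


def build_scenario_a() -> Scenario:
    """Sickroom + gallery: drink water, pass the door, meet a walking person."""
    door_y = 1.0
    obstacles = [
        box_obstacle(-WALL, -WALL, 0.0, 4.1),           # west wall
        box_obstacle(-WALL, -WALL, 9.1, 0.0),           # south wall
        box_obstacle(-WALL, 4.0, 4.1, 4.1),             # room north wall
        box_obstacle(4.1, 2.0, 9.1, 2.1),               # gallery north wall
        box_obstacle(9.0, -WALL, 9.1, 2.1),             # east wall
        box_obstacle(0.3, 2.2, 0.9, 3.4),               # desk slab
    ]
    obstacles += wall_with_door(4.0, 0.0, 4.1, 4.0,
                                door_centre=door_y, door_width=DOOR_WIDTH)
    agents = [
        WorldObject(1, "desk", (0.6, 2.8), height=0.75, extent=(0.6, 1.2)),
        WorldObject(2, "bottle", (0.88, 2.55), height=0.97, radius=0.03,
                    z_base=0.75),
        WorldObject(3, "bottle", (0.88, 3.15), height=0.97, radius=0.03,
                    z_base=0.75),
        WorldObject(4, "opened_door", (4.05, door_y), height=2.0,
                    extent=(0.02, DOOR_WIDTH)),
        WorldObject(5, "person", (7.2, 1.1), height=1.7, radius=0.25),
    ]
    world = World(bounds=(-WALL, -WALL, 9.1, 4.1), obstacles=obstacles,
                  doorways=[Doorway((4.05, door_y), DOOR_WIDTH, (1.0, 0.0))],
                  agents=agents)
    tasks = [
        TaskStep("auto", "goto", target_class="desk"),
        TaskStep("auto", "pick", target_class="bottle"),
        TaskStep(None, "drink", duration=5.0),
        TaskStep("command", "command", command="backward", amount=1.3),
        TaskStep("command", "command", command="rotate_right", amount=np.pi / 2),
        TaskStep("auto", "pass_door", target_class="opened_door"),
        TaskStep("command", "command", command="rotate_right", amount=0.2),
        TaskStep("auto", "goto", target_class="person", dynamic=True),
        TaskStep(None, "conversation", duration=5.0),
    ]
    return Scenario(
        name="A", world=world, start_pose=np.array([2.4, 2.8, np.pi]),
        tasks=tasks, walk_targets={5: (8.2, 1.1)}, walk_speed=0.5,
    )


def build_scenario_b() -> Scenario:
    """Two furnished rooms: meet a person, visit a chair, fetch a bottle."""
    door_y = 2.0
    obstacles = [
        box_obstacle(-WALL, -WALL, 0.0, 4.1),           # west wall
        box_obstacle(-WALL, -WALL, 9.1, 0.0),           # south wall
        box_obstacle(-WALL, 4.0, 9.1, 4.1),             # north wall
        box_obstacle(9.0, -WALL, 9.1, 4.1),             # east wall
        box_obstacle(8.1, 1.4, 8.7, 2.6),               # desk slab (room 2)
        box_obstacle(1.2, 0.2, 1.8, 0.8),               # paper boxes
    ]
    obstacles += wall_with_door(5.0, 0.0, 5.1, 4.0,
                                door_centre=door_y, door_width=DOOR_WIDTH)
    agents = [
        WorldObject(1, "person", (3.2, 3.0), height=1.7, radius=0.25),
        WorldObject(2, "chair", (4.6, 2.6), height=0.9, radius=0.25),
        WorldObject(3, "opened_door", (5.05, door_y), height=2.0,
                    extent=(0.02, DOOR_WIDTH)),
        WorldObject(4, "desk", (8.4, 2.0), height=0.75, extent=(0.6, 1.2),
                    theta=0.0),
        WorldObject(5, "bottle", (8.12, 2.0), height=0.97, radius=0.03,
                    z_base=0.75),
    ]
    world = World(bounds=(-WALL, -WALL, 9.1, 4.1), obstacles=obstacles,
                  doorways=[Doorway((5.05, door_y), DOOR_WIDTH, (1.0, 0.0))],
                  agents=agents)
    tasks = [
        TaskStep("auto", "goto", target_class="person", dynamic=True),
        TaskStep(None, "conversation", duration=5.0),
        TaskStep("auto", "goto", target_class="chair"),
        TaskStep("command", "command", command="rotate_right", amount=0.25),
        TaskStep("auto", "pass_door", target_class="opened_door"),
        TaskStep("command", "command", command="rotate_right", amount=0.2),
        TaskStep("auto", "goto", target_class="desk"),
        TaskStep("auto", "pick", target_class="bottle"),
        TaskStep(None, "drink", duration=5.0),
    ]
    return Scenario(
        name="B", world=world, start_pose=np.array([1.0, 2.0, 0.0]),
        tasks=tasks, walk_targets={1: (4.0, 3.2)}, walk_speed=0.5,
    )


def get_scenario(name: str) -> Scenario:
    builders = {"A": build_scenario_a, "B": build_scenario_b}
    if name.upper() not in builders:
        raise ValueError(f"unknown scenario {name!r}; available: A, B")
    return builders[name.upper()]()
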