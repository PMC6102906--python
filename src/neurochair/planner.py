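"""Target-solution planning and the shared-control state machine.

The ten object classes partition into four solution groups: conversation
targets (person/chair/sofa, stop 0.80 m away facing the target), approach
targets (bed/closed door/desk, stop 0.20 m away), passage (opened door:
reach it, then pass through along its normal), and manipulation (electric
switch/bottle/cup: translate the holonomic chassis until the target enters
the arm workspace, then press or pick).  The target's vertical coordinate is
checked against the arm workspace *before* any adjustment - the chassis can
only translate in the plane, so an out-of-reach height rejects the
operation outright.

The state machine alternately pre-activates auto-control and command-control
every 3 s; a jaw-clench validation selects the pre-activated mode, a P300
prediction plus a second validation starts execution, and task completion,
collision or a planner deadloop resets to mode selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .geometry import unit, wrap_angle
from .perception import TargetEstimate
from .world import CLASSES

CONVERSATION_DISTANCE = 0.80  # m, comfortable communication standoff
APPROACH_DISTANCE = 0.20      # m, close-operation standoff
#: Goal distance beyond the doorway centre.  Half the 1.2 m footprint length
#: (0.6 m) just clears the door plane at rest; the extra 0.2 m also clears
#: the wall from the footprint's in-place rotation envelope (circumscribed
#: radius 0.69 m), so the chassis can turn immediately after passing.
PASS_THROUGH_CLEARANCE = 0.80
MODE_WINDOW = 3.0             # s a pre-activated mode persists

#: Class priority, highest first (person outranks chair; ties broken by
#: distance).  Only person > chair is prescribed; the rest is a configurable
#: convention ordering actionable/urgent classes ahead of furniture.
DEFAULT_PRIORITY = (
    "person", "opened_door", "closed_door", "bottle", "cup",
    "electric_switch", "chair", "sofa", "desk", "bed",
)

#: The six direct wheelchair commands available in command-control mode.
COMMANDS = ("forward", "backward", "translate_left", "translate_right",
            "rotate_left", "rotate_right")


class Primitive(Enum):
    NAV_TO_POSE = "NAV_TO_POSE"
    PASS_THROUGH = "PASS_THROUGH"
    ADJUST_UNTIL_IN_WORKSPACE = "ADJUST_UNTIL_IN_WORKSPACE"
    ARM_PRESS = "ARM_PRESS"
    ARM_PICK = "ARM_PICK"
    ARM_TO_MOUTH = "ARM_TO_MOUTH"


@dataclass(frozen=True)
class SolutionRule:
    name: str
    classes: frozenset[str]
    approach_distance: float | None
    actions: tuple[Primitive, ...]


DEFAULT_RULES = (
    SolutionRule("conversation", frozenset({"person", "chair", "sofa"}),
                 CONVERSATION_DISTANCE, (Primitive.NAV_TO_POSE,)),
    SolutionRule("approach", frozenset({"bed", "closed_door", "desk"}),
                 APPROACH_DISTANCE, (Primitive.NAV_TO_POSE,)),
    SolutionRule("passage", frozenset({"opened_door"}),
                 PASS_THROUGH_CLEARANCE,
                 (Primitive.NAV_TO_POSE, Primitive.PASS_THROUGH)),
    SolutionRule("manipulation", frozenset({"electric_switch", "bottle", "cup"}),
                 None,
                 (Primitive.ADJUST_UNTIL_IN_WORKSPACE,)),
)


def rule_for_class(cls: str, rules=DEFAULT_RULES) -> SolutionRule:
    for r in rules:
        if cls in r.classes:
            return r
    raise ValueError(f"no solution rule covers class {cls!r}")


def check_rules_partition(rules=DEFAULT_RULES) -> None:
    covered: list[str] = []
    for r in rules:
        covered.extend(r.classes)
    if sorted(covered) != sorted(CLASSES):
        raise ValueError("solution rules must partition the 10 classes exactly")


@dataclass(frozen=True)
class ArmWorkspace:
    """Reachable end-effector box in the arm frame, metres.

    ``arm_origin_body`` places the arm frame in the wheelchair body frame
    (the arm is mounted on the left armrest, ~0.6 m above the floor).
    """

    x_range: tuple[float, float] = (-0.200, 0.0)
    y_range: tuple[float, float] = (0.0, 0.350)
    z_range: tuple[float, float] = (-0.150, 0.300)
    arm_origin_body: tuple[float, float, float] = (0.30, 0.30, 0.60)

    def __post_init__(self) -> None:
        for lo, hi in (self.x_range, self.y_range, self.z_range):
            if lo >= hi:
                raise ValueError("workspace ranges need min < max")

    def z_reachable(self, z_world: float) -> bool:
        z_arm = z_world - self.arm_origin_body[2]
        return self.z_range[0] <= z_arm <= self.z_range[1]

    def centre_body(self) -> np.ndarray:
        """Workspace centre, in the body frame."""
        off = np.asarray(self.arm_origin_body)
        mid = np.array([np.mean(self.x_range), np.mean(self.y_range),
                        np.mean(self.z_range)])
        return off + mid

    def grasp_point_body(self) -> np.ndarray:
        """Preferred in-workspace xy for a grasp target, in the body frame.

        Biased outboard (70% along the lateral range) so the chassis keeps
        clear of the furniture the object usually stands on.
        """
        off = np.asarray(self.arm_origin_body)
        return np.array([
            off[0] + np.mean(self.x_range),
            off[1] + self.y_range[0] + 0.7 * (self.y_range[1] - self.y_range[0]),
        ])


class SolutionRejected(RuntimeError):
    """Target not executable by the arm (e.g. height outside the workspace)."""


@dataclass(frozen=True)
class Action:
    primitive: Primitive
    params: dict


@dataclass(frozen=True)
class Solution:
    """Planned response to a confirmed target.

    ``goal_pose`` for the standoff rules (conversation/approach) locates the
    chassis *front* docking point exactly at the rule's approach distance
    from the target centre; passage and manipulation goals are chassis-centre
    poses (``reference == "centre"``).
    """

    rule: str
    goal_pose: np.ndarray  # (x, y, theta) wheelchair goal
    actions: tuple[Action, ...]
    reference: str = "front"  # "front" | "centre"


@dataclass(frozen=True)
class PrioritizedTargets:
    """At most six targets, display indices 0-5, highest priority first."""

    targets: tuple[TargetEstimate, ...]

    @property
    def default_selection(self) -> TargetEstimate | None:
        return self.targets[0] if self.targets else None

    def index_of(self, target_id: int) -> int:
        for i, t in enumerate(self.targets):
            if t.target_id == target_id:
                return i
        raise KeyError(f"target id {target_id} not displayed")


def prioritize_targets(
    estimates,
    wheelchair_pose,
    priority=DEFAULT_PRIORITY,
    max_items: int = 6,
) -> PrioritizedTargets:
    """Sort by (class rank, distance ascending) and keep the first six."""
    rank = {c: i for i, c in enumerate(priority)}
    pos = np.asarray(wheelchair_pose[:2], dtype=float)

    def key(t: TargetEstimate):
        return (rank.get(t.cls, len(rank)),
                float(np.linalg.norm(np.asarray(t.position[:2]) - pos)))

    ordered = tuple(sorted(estimates, key=key)[:max_items])
    return PrioritizedTargets(ordered)


def _facing_heading(goal_xy, target_xy) -> float:
    d = np.asarray(target_xy) - np.asarray(goal_xy)
    return float(np.arctan2(d[1], d[0]))


def plan_solution(
    target: TargetEstimate,
    wheelchair_pose,
    workspace: ArmWorkspace | None = None,
    rules=DEFAULT_RULES,
) -> Solution:
    """Map a confirmed target to a goal pose and action sequence.

    Standoff goals lie along the target's orientation vector (which points
    back at the wheelchair, so the goal is between target and wheelchair)
    at the rule's approach distance, heading facing the target centre.
    """
    workspace = workspace or ArmWorkspace()
    rule = rule_for_class(target.cls, rules)
    centre = np.asarray(target.position[:2], dtype=float)
    orient = unit(np.asarray(target.orientation[:2], dtype=float))

    if rule.name in ("conversation", "approach"):
        goal_xy = centre + rule.approach_distance * orient
        theta = _facing_heading(goal_xy, centre)
        goal = np.array([goal_xy[0], goal_xy[1], theta])
        return Solution(rule.name, goal, (
            Action(Primitive.NAV_TO_POSE, {"pose": goal.tolist()}),
        ))

    if rule.name == "passage":
        # Reach the doorway along its normal, then continue beyond it.
        pre_xy = centre + PASS_THROUGH_CLEARANCE * orient
        theta = _facing_heading(pre_xy, centre)
        pre = np.array([pre_xy[0], pre_xy[1], theta])
        beyond_xy = centre - PASS_THROUGH_CLEARANCE * orient
        beyond = np.array([beyond_xy[0], beyond_xy[1], theta])
        return Solution(rule.name, beyond, (
            Action(Primitive.NAV_TO_POSE, {"pose": pre.tolist()}),
            Action(Primitive.PASS_THROUGH, {"pose": beyond.tolist()}),
        ), reference="centre")

    # manipulation: z feasibility first (the chassis cannot change height)
    z = float(target.position[2])
    if not workspace.z_reachable(z):
        z_arm = z - workspace.arm_origin_body[2]
        raise SolutionRejected(
            f"{target.cls!r} at z={z_arm * 1000:.0f} mm in the arm frame is outside "
            f"the workspace z-range {tuple(int(v * 1000) for v in workspace.z_range)} mm"
        )
    # Translate the chassis so the target lands at the workspace centre,
    # heading chosen to put the target on the left, where the arm sits.
    f = unit(centre - np.asarray(wheelchair_pose[:2], dtype=float))
    theta = float(np.arctan2(-f[0], f[1]))
    want_body = workspace.grasp_point_body()
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    goal_xy = centre - R @ want_body
    goal = np.array([goal_xy[0], goal_xy[1], theta])
    arm = (Action(Primitive.ARM_PRESS, {"target": target.position.tolist()}),) \
        if target.cls == "electric_switch" else (
            Action(Primitive.ARM_PICK, {"target": target.position.tolist()}),
            Action(Primitive.ARM_TO_MOUTH, {}),
        )
    return Solution("manipulation", goal, (
        Action(Primitive.ADJUST_UNTIL_IN_WORKSPACE, {"pose": goal.tolist()}),
    ) + arm, reference="centre")


# ---------------------------------------------------------------------------
# shared-control state machine


class SMState(Enum):
    MODE_SELECT = "MODE_SELECT"
    P300_SELECT = "P300_SELECT"
    AWAIT_VALIDATION = "AWAIT_VALIDATION"
    EXECUTING = "EXECUTING"
    RESET = "RESET"


class StateMachineError(RuntimeError):
    pass


@dataclass(frozen=True)
class ControlState:
    state: SMState = SMState.MODE_SELECT
    preactivated_mode: str = "auto"       # "auto" | "command"
    mode_window_deadline: float | None = None
    targets_present: bool = True
    active_mode: str | None = None        # mode confirmed by validation
    selected_item: int | None = None

    def __post_init__(self) -> None:
        if self.preactivated_mode not in ("auto", "command"):
            raise ValueError("preactivated_mode must be 'auto' or 'command'")


def sm_step(cs: ControlState, event: str, t: float | None = None, **payload) -> ControlState:
    """Advance the shared-control state machine by one event.

    Events: ``tick`` (needs t), ``targets_present`` (present=bool),
    ``validation_fired``, ``p300_output`` (item=int), ``task_done``,
    ``collision``, ``deadloop``.
    """
    if event == "targets_present":
        present = bool(payload.get("present", True))
        cs = replace(cs, targets_present=present)
        if not present and cs.state == SMState.MODE_SELECT:
            cs = replace(cs, preactivated_mode="command")
        return cs

    if cs.state == SMState.MODE_SELECT:
        if event == "tick":
            if t is None:
                raise ValueError("tick event requires a time")
            if cs.mode_window_deadline is None:
                return replace(cs, mode_window_deadline=t + MODE_WINDOW)
            if t >= cs.mode_window_deadline:
                # alternate; without targets, stay on command control
                nxt = "command" if not cs.targets_present else (
                    "command" if cs.preactivated_mode == "auto" else "auto")
                return replace(cs, preactivated_mode=nxt,
                               mode_window_deadline=cs.mode_window_deadline + MODE_WINDOW)
            return cs
        if event == "validation_fired":
            return replace(cs, state=SMState.P300_SELECT,
                           active_mode=cs.preactivated_mode,
                           mode_window_deadline=None)

    elif cs.state == SMState.P300_SELECT:
        if event == "tick":
            return cs
        if event == "p300_output":
            return replace(cs, state=SMState.AWAIT_VALIDATION,
                           selected_item=int(payload["item"]))

    elif cs.state == SMState.AWAIT_VALIDATION:
        if event == "tick":
            return cs
        if event == "p300_output":  # a further trial refines the prediction
            return replace(cs, selected_item=int(payload["item"]))
        if event == "validation_fired":
            return replace(cs, state=SMState.EXECUTING)

    elif cs.state == SMState.EXECUTING:
        if event == "tick":
            return cs
        if event == "validation_fired":
            if cs.active_mode == "command":
                # a second validation ceases command execution
                return replace(cs, state=SMState.RESET)
            return cs  # spurious validation in auto mode: ignored (FV logged)
        if event in ("task_done", "collision", "deadloop"):
            return replace(cs, state=SMState.RESET)

    elif cs.state == SMState.RESET:
        if event == "tick":
            if t is None:
                raise ValueError("tick event requires a time")
            pre = "auto" if cs.targets_present else "command"
            return ControlState(state=SMState.MODE_SELECT, preactivated_mode=pre,
                                mode_window_deadline=t + MODE_WINDOW,
                                targets_present=cs.targets_present)

    raise StateMachineError(f"event {event!r} is illegal in state {cs.state.value}")
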