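"""Simulated depth-camera sensing, target localization and orientation.

Sensing stands in for an RGB-D camera plus an object detector: each object
inside the camera's field of view yields a pixel bounding box and a noisy
3D point cloud sampled on its camera-facing surface.  Localization shrinks
the bounding box to 60% (linearly, about its centre), keeps the cloud points
whose pixels fall inside it, drops everything below 10 cm off the floor, and
averages the survivors.  Orientation in the horizontal plane is the first
principal axis of the projected cloud - or its in-plane orthogonal,
whichever makes the smaller angle with the wheelchair-to-target vector f -
signed to point back at the wheelchair (face-to-face convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import body_to_world, line_angle, unit, world_to_body
from .world import World, WorldObject

BBOX_SHRINK = 0.6          # linear, per side, about the bbox centre
FLOOR_CUTOFF = 0.10        # m; points below this height are discarded
DEGENERACY_RATIO = 1.2     # min singular-value ratio for a usable axis


class LocalizationError(RuntimeError):
    """No usable points inside the shrunk bounding box (EP event downstream)."""


class TrackingFailure(RuntimeError):
    """The tracked object left the camera field of view (EP event downstream)."""


@dataclass(frozen=True)
class CameraModel:
    width: int = 640
    height: int = 480
    hfov_deg: float = 57.0
    mount_height: float = 1.5
    depression_deg: float = 37.0  # the plausible value for a 1.5 m mount
    max_range: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.hfov_deg < 180:
            raise ValueError("horizontal field of view must be in (0, 180) deg")

    @property
    def fx(self) -> float:
        return (self.width / 2) / np.tan(np.radians(self.hfov_deg) / 2)

    def basis(self) -> np.ndarray:
        """Rows = camera right / down / forward axes, in the body frame."""
        d = np.radians(self.depression_deg)
        z_c = np.array([np.cos(d), 0.0, -np.sin(d)])   # optical axis
        x_c = np.array([0.0, -1.0, 0.0])               # image right
        y_c = np.cross(z_c, x_c)                       # image down
        return np.vstack([x_c, y_c, z_c])

    def project(self, points_body: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates (u, v) and a validity mask for body-frame points."""
        p = np.atleast_2d(points_body) - np.array([0.0, 0.0, self.mount_height])
        q = p @ self.basis().T
        depth = q[:, 2]
        ok = depth > 1e-6
        u = np.full(len(q), np.nan)
        v = np.full(len(q), np.nan)
        u[ok] = self.width / 2 + self.fx * q[ok, 0] / depth[ok]
        v[ok] = self.height / 2 + self.fx * q[ok, 1] / depth[ok]
        return np.column_stack([u, v]), ok

    def sees(self, position_body_xy: np.ndarray) -> bool:
        x, y = float(position_body_xy[0]), float(position_body_xy[1])
        rng = np.hypot(x, y)
        if x <= 0 or rng > self.max_range:
            return False
        return abs(np.arctan2(y, x)) <= np.radians(self.hfov_deg) / 2


@dataclass(frozen=True)
class Detection:
    cls: str
    bbox: tuple[float, float, float, float]  # (x, y, w, h), top-left origin
    confidence: float
    index: int | None = None     # display number 0-5 once prioritized
    object_id: int | None = None  # simulation ground-truth provenance

    def __post_init__(self) -> None:
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise ValueError("bounding box must have positive extent")


@dataclass(frozen=True)
class PointCloud:
    """Body-frame 3D points with per-point pixel provenance."""

    points: np.ndarray               # (N, 3)
    pixels: np.ndarray | None = None  # (N, 2)
    object_ids: np.ndarray | None = None


@dataclass(frozen=True)
class TargetEstimate:
    target_id: int
    cls: str
    position: np.ndarray           # world frame (x, y, z)
    orientation: np.ndarray        # unit 2D vector, world frame
    f_vector: np.ndarray           # unit 2D wheelchair->target, world frame
    last_update: float = 0.0
    degenerate: bool = False


def _sample_surface(obj: WorldObject, cam_xy_world: np.ndarray, n: int, rng) -> np.ndarray:
    """World-frame points on the object's camera-facing surface."""
    z = rng.uniform(obj.z_base, obj.height, n)
    if obj.radius is not None:
        phi0 = np.arctan2(*(cam_xy_world - obj.position)[::-1])
        phi = phi0 + rng.uniform(-np.pi / 2, np.pi / 2, n)
        xy = obj.position + obj.radius * np.column_stack([np.cos(phi), np.sin(phi)])
    else:
        w, d = obj.extent
        c, s = np.cos(obj.theta), np.sin(obj.theta)
        R = np.array([[c, -s], [s, c]])
        corners = np.array([[-w / 2, -d / 2], [w / 2, -d / 2],
                            [w / 2, d / 2], [-w / 2, d / 2]]) @ R.T + obj.position
        edges = [(corners[i], corners[(i + 1) % 4]) for i in range(4)]
        visible = []
        for a, b in edges:
            mid = (a + b) / 2
            normal = np.array([(b - a)[1], -(b - a)[0]])
            if np.dot(normal, cam_xy_world - mid) > 0:
                visible.append((a, b, np.linalg.norm(b - a)))
        if not visible:
            visible = [(a, b, np.linalg.norm(b - a)) for a, b in edges]
        lengths = np.array([e[2] for e in visible])
        pick = rng.choice(len(visible), size=n, p=lengths / lengths.sum())
        t = rng.uniform(0, 1, n)
        xy = np.array([visible[k][0] + t[i] * (visible[k][1] - visible[k][0])
                       for i, k in enumerate(pick)])
    return np.column_stack([xy, z])


def sense_object(
    obj: WorldObject,
    wheelchair_pose,
    camera: CameraModel,
    rng,
    n_points: int = 300,
    noise_sigma: float = 0.01,
) -> tuple[Detection | None, PointCloud]:
    """Detection + surface point cloud for a single object; None if unseen."""
    body_xy = world_to_body(obj.position, wheelchair_pose)[0]
    if not camera.sees(body_xy):
        return None, PointCloud(np.empty((0, 3)), np.empty((0, 2)),
                                np.empty(0, dtype=int))
    pts_w = _sample_surface(obj, np.asarray(wheelchair_pose[:2]), n_points, rng)
    pts_b = np.column_stack([world_to_body(pts_w[:, :2], wheelchair_pose), pts_w[:, 2]])
    if noise_sigma > 0:
        pts_b = pts_b + rng.normal(0.0, noise_sigma, pts_b.shape)
    pixels, ok = camera.project(pts_b)
    pts_b, pixels = pts_b[ok], pixels[ok]
    inside = ((pixels[:, 0] >= 0) & (pixels[:, 0] < camera.width)
              & (pixels[:, 1] >= 0) & (pixels[:, 1] < camera.height))
    if inside.sum() < 3:
        return None, PointCloud(np.empty((0, 3)), np.empty((0, 2)),
                                np.empty(0, dtype=int))
    pts_b, pixels = pts_b[inside], pixels[inside]
    x0, y0 = pixels.min(axis=0)
    x1, y1 = pixels.max(axis=0)
    det = Detection(
        cls=obj.cls,
        bbox=(float(x0), float(y0), float(max(x1 - x0, 1.0)), float(max(y1 - y0, 1.0))),
        confidence=1.0,
        object_id=obj.object_id,
    )
    ids = np.full(len(pts_b), obj.object_id, dtype=int)
    return det, PointCloud(pts_b, pixels, ids)


def simulate_sensing(
    world: World,
    wheelchair_pose,
    camera: CameraModel | None = None,
    seed=None,
    miss_rate: float = 0.0,
    false_rate: float = 0.0,
    n_points: int = 300,
    noise_sigma: float = 0.01,
) -> tuple[list[Detection], PointCloud]:
    """One sensing frame: detections plus the merged scene point cloud.

    Objects outside the field of view or beyond range never appear; visible
    objects are missed with probability ``miss_rate`` and a spurious
    detection is injected with probability ``false_rate``.
    """
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    detections: list[Detection] = []
    clouds: list[PointCloud] = []
    for obj in world.agents:
        det, cloud = sense_object(obj, wheelchair_pose, camera, rng,
                                  n_points, noise_sigma)
        if det is None:
            continue
        if cloud.points.size:
            clouds.append(cloud)
        if rng.uniform() < miss_rate:
            continue
        detections.append(det)
    if rng.uniform() < false_rate:
        w = rng.uniform(20, 120)
        h = rng.uniform(20, 120)
        x = rng.uniform(0, camera.width - w)
        y = rng.uniform(0, camera.height - h)
        cls = world.agents[0].cls if world.agents else "chair"
        detections.append(Detection(cls, (x, y, w, h), 0.3, object_id=None))
    if clouds:
        merged = PointCloud(
            np.vstack([c.points for c in clouds]),
            np.vstack([c.pixels for c in clouds]),
            np.concatenate([c.object_ids for c in clouds]),
        )
    else:
        merged = PointCloud(np.empty((0, 3)), np.empty((0, 2)), np.empty(0, dtype=int))
    return detections, merged


def shrink_bbox(bbox, factor: float = BBOX_SHRINK):
    """Shrink (x, y, w, h) linearly about its centre."""
    x, y, w, h = bbox
    return (x + w * (1 - factor) / 2, y + h * (1 - factor) / 2,
            w * factor, h * factor)


def localize_target(
    detection: Detection,
    cloud: PointCloud,
    camera: CameraModel | None = None,
) -> np.ndarray:
    """Body-frame centroid of the shrunk-bbox, above-floor cloud points."""
    if cloud.pixels is None:
        raise ValueError("point cloud lacks pixel provenance")
    sx, sy, sw, sh = shrink_bbox(detection.bbox)
    px = cloud.pixels
    inside = ((px[:, 0] >= sx) & (px[:, 0] <= sx + sw)
              & (px[:, 1] >= sy) & (px[:, 1] <= sy + sh))
    pts = cloud.points[inside]
    pts = pts[pts[:, 2] >= FLOOR_CUTOFF]
    if len(pts) == 0:
        raise LocalizationError(
            f"no points survive bbox shrink + floor filter for {detection.cls!r}"
        )
    return pts.mean(axis=0)


def estimate_orientation(points, wheelchair_position) -> tuple[np.ndarray, bool]:
    """Horizontal orientation of a target from its point cloud.

    Returns ``(unit_vector, degenerate)``.  The vector is the principal axis
    v or its orthogonal vn, whichever subtends the smaller (sign-invariant)
    angle with the wheelchair-to-target vector f, signed so that it points
    toward the wheelchair (dot(orientation, f) <= 0).  Near-isotropic clouds
    (singular-value ratio < 1.2) return -f with the degeneracy flag set.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    centre = pts.mean(axis=0)
    f = unit(centre - np.asarray(wheelchair_position[:2], dtype=float))
    centred = pts - centre
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] <= 0 or svals[0] / max(svals[1], 1e-300) < DEGENERACY_RATIO:
        if svals[0] < 1e-12:  # all points coincide: no axis at all
            return -f, True
        if svals[0] / max(svals[1], 1e-300) < DEGENERACY_RATIO:
            return -f, True
    v = vt[0]
    vn = np.array([-v[1], v[0]])
    axis = v if line_angle(v, f) <= line_angle(vn, f) else vn
    if np.dot(axis, f) > 0:
        axis = -axis
    return unit(axis), False


def make_target_estimate(
    detection: Detection,
    cloud: PointCloud,
    camera: CameraModel,
    wheelchair_pose,
    t: float = 0.0,
) -> TargetEstimate:
    """Full world-frame target estimate from one sensing frame."""
    pos_b = localize_target(detection, cloud, camera)
    pos_w_xy = body_to_world(pos_b[:2], wheelchair_pose)[0]
    own = (cloud.object_ids == detection.object_id
           if detection.object_id is not None and cloud.object_ids is not None
           else np.ones(len(cloud.points), dtype=bool))
    pts_w = body_to_world(cloud.points[own][:, :2], wheelchair_pose)
    orientation, degenerate = estimate_orientation(pts_w, wheelchair_pose[:2])
    f = unit(pos_w_xy - np.asarray(wheelchair_pose[:2]))
    return TargetEstimate(
        target_id=detection.object_id if detection.object_id is not None else -1,
        cls=detection.cls,
        position=np.array([pos_w_xy[0], pos_w_xy[1], pos_b[2]]),
        orientation=orientation,
        f_vector=f,
        last_update=t,
        degenerate=degenerate,
    )


def track_update(
    estimate: TargetEstimate,
    world: World,
    wheelchair_pose,
    camera: CameraModel | None = None,
    t: float = 0.0,
    seed=None,
    noise_sigma: float = 0.01,
) -> TargetEstimate:
    """Refresh a confirmed target from a new simulated frame.

    Raises :class:`TrackingFailure` when the true object has left the camera
    field of view (the tracked bbox cannot be updated), which downstream
    counts as an environment-perception deduction and aborts the task.
    """
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    obj = world.object_by_id(estimate.target_id)
    det, cloud = sense_object(obj, wheelchair_pose, camera, rng,
                              noise_sigma=noise_sigma)
    if det is None:
        raise TrackingFailure(
            f"target {estimate.cls!r} (id {estimate.target_id}) left the field of view"
        )
    try:
        new = make_target_estimate(det, cloud, camera, wheelchair_pose, t)
    except LocalizationError as err:
        raise TrackingFailure(str(err)) from err
    return replace(new, target_id=estimate.target_id)
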