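"""Planar frame conventions and small helpers.

Body frame: x forward, y left, z up, metres.  World pose = (x, y, theta)
with theta counter-clockwise from world +x.  Pixel bounding boxes use a
top-left origin, (x, y, w, h).
"""

from __future__ import annotations

import numpy as np


def rot2d(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def world_to_body(points_xy: np.ndarray, pose) -> np.ndarray:
    """Transform world-frame xy points into the body frame of ``pose``."""
    p = np.atleast_2d(points_xy) - np.asarray(pose[:2])
    return p @ rot2d(pose[2])  # R(-theta) @ p^T == p @ R(theta)


def body_to_world(points_xy: np.ndarray, pose) -> np.ndarray:
    p = np.atleast_2d(points_xy)
    return p @ rot2d(pose[2]).T + np.asarray(pose[:2])


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    return float(np.pi - np.mod(np.pi - a, 2 * np.pi))


def line_angle(u, v) -> float:
    """Sign-invariant angle between the lines spanned by u and v, in [0, pi/2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise the zero vector")
    return v / n
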