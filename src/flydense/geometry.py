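"""Scene geometry: the bottle (an axis-aligned box) and idealized pinhole cameras.

Coordinate conventions
----------------------
World ("bottle") frame: right-handed, z up, origin at the center of the
bottle floor.  The bottle occupies x in [-w/2, w/2], y in [-d/2, d/2],
z in [0, h].

Pixels are 0-based, x to the right, y down.  A camera maps a world point X to
camera coordinates Xc = R (X - C) with C the camera center, then to pixels
(f * Xc0 / Xc2 + cx, f * Xc1 / Xc2 + cy); points with Xc2 <= 0 are behind
the camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BottleGeometry:
    """Axis-aligned box standing in for the culture-flask chamber.

    ``wall_margin`` is the proximity band (m) within which a point counts as
    sitting on a surface rather than being in free space.
    """

    width: float = 0.11
    depth: float = 0.07
    height: float = 0.23
    wall_margin: float = 0.005

    def __post_init__(self) -> None:
        dims = (self.width, self.depth, self.height)
        if any(d <= 0 for d in dims):
            raise ValueError("bottle dimensions must be positive")
        if not (0 < self.wall_margin < min(dims) / 4):
            raise ValueError("wall_margin must be positive and < min(dims)/4")

    def contains(self, points: np.ndarray, dilation: float = 0.0) -> np.ndarray:
        """Boolean mask: which (n,3) points lie inside the (dilated) box."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        hw, hd = self.width / 2 + dilation, self.depth / 2 + dilation
        return (
            (np.abs(p[:, 0]) <= hw)
            & (np.abs(p[:, 1]) <= hd)
            & (p[:, 2] >= -dilation)
            & (p[:, 2] <= self.height + dilation)
        )

    def surface_class(self, point: np.ndarray, margin: float | None = None) -> str:
        """'on_floor', 'on_wall' (side walls or ceiling) or 'free_space'.

        Floor takes precedence in corners so that a fly resting at the base of
        a wall is counted as grounded.
        """
        x, y, z = np.asarray(point, dtype=float)
        m = self.wall_margin if margin is None else margin
        if z <= m:
            return "on_floor"
        near_side = (self.width / 2 - abs(x) <= m) or (self.depth / 2 - abs(y) <= m)
        near_ceiling = self.height - z <= m
        if near_side or near_ceiling:
            return "on_wall"
        return "free_space"

    def to_dict(self) -> dict:
        return {
            "width_m": self.width,
            "depth_m": self.depth,
            "height_m": self.height,
            "wall_margin_m": self.wall_margin,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BottleGeometry":
        return cls(
            width=float(d["width_m"]),
            depth=float(d["depth_m"]),
            height=float(d["height_m"]),
            wall_margin=float(d.get("wall_margin_m", 0.005)),
        )


@dataclass(frozen=True)
class CameraModel:
    """Idealized pinhole camera with square pixels and no distortion."""

    camera_id: str
    focal_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]
    rotation: np.ndarray  # (3,3) world->camera
    translation: np.ndarray  # (3,) t = -R C

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        if self.focal_px <= 0:
            raise ValueError("focal_px must be positive")
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.rotation.T @ self.translation

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project (n,3) world points.

        Returns (pixels (n,2), depth (n,)); depth <= 0 means behind the camera.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        cam = p @ self.rotation.T + self.translation
        depth = cam[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.focal_px * cam[:, 0] / depth + self.principal_point[0]
            v = self.focal_px * cam[:, 1] / depth + self.principal_point[1]
        return np.column_stack([u, v]), depth

    def in_frame(self, pixels: np.ndarray, depth: np.ndarray) -> np.ndarray:
        """Mask of projections that land inside the image and in front of the camera."""
        px = np.atleast_2d(pixels)
        w, h = self.image_size
        return (
            (depth > 0)
            & (px[:, 0] >= 0)
            & (px[:, 0] <= w - 1)
            & (px[:, 1] >= 0)
            & (px[:, 1] <= h - 1)
        )

    def rays(self, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Back-project (n,2) pixels to world rays (origins (n,3), unit dirs (n,3))."""
        px = np.atleast_2d(np.asarray(pixels, dtype=float))
        cx, cy = self.principal_point
        d_cam = np.column_stack(
            [
                (px[:, 0] - cx) / self.focal_px,
                (px[:, 1] - cy) / self.focal_px,
                np.ones(len(px)),
            ]
        )
        d_world = d_cam @ self.rotation  # R^T applied row-wise
        d_world /= np.linalg.norm(d_world, axis=1, keepdims=True)
        origins = np.broadcast_to(self.center, d_world.shape).copy()
        return origins, d_world

    @classmethod
    def look_at(
        cls,
        camera_id: str,
        position: np.ndarray,
        target: np.ndarray,
        focal_px: float = 1000.0,
        image_size: tuple[int, int] = (1920, 1080),
        principal_point: tuple[float, float] | None = None,
    ) -> "CameraModel":
        """Build a camera at ``position`` whose optical axis points at ``target``."""
        position = np.asarray(position, dtype=float)
        target = np.asarray(target, dtype=float)
        forward = target - position
        n = np.linalg.norm(forward)
        if n == 0:
            raise ValueError("camera position and target coincide")
        forward /= n
        world_down = np.array([0.0, 0.0, -1.0])
        right = np.cross(world_down, forward)
        rn = np.linalg.norm(right)
        if rn < 1e-12:  # looking straight up/down; pick an arbitrary right
            right = np.array([1.0, 0.0, 0.0])
        else:
            right /= rn
        down = np.cross(forward, right)
        R = np.vstack([right, down, forward])
        t = -R @ position
        if principal_point is None:
            principal_point = ((image_size[0] - 1) / 2.0, (image_size[1] - 1) / 2.0)
        return cls(camera_id, focal_px, principal_point, image_size, R, t)

    def to_dict(self) -> dict:
        return {
            "camera_id": self.camera_id,
            "focal_px": float(self.focal_px),
            "principal_point": [float(v) for v in self.principal_point],
            "image_size": [int(v) for v in self.image_size],
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            camera_id=str(d["camera_id"]),
            focal_px=float(d["focal_px"]),
            principal_point=tuple(d["principal_point"]),
            image_size=tuple(d["image_size"]),
            rotation=np.asarray(d["rotation"], dtype=float),
            translation=np.asarray(d["translation"], dtype=float),
        )


def default_stereo_rig(
    bottle: BottleGeometry | None = None,
    distance: float = 0.45,
    focal_px: float = 1000.0,
) -> tuple[CameraModel, CameraModel]:
    """Two cameras ~90 degrees apart, both aimed at the bottle mid-height.

    Mimics the two-webcam rig: one camera in front of the bottle, one to the
    side, each far enough back that the whole bottle fits the frame.
    """
    bottle = bottle or BottleGeometry()
    target = np.array([0.0, 0.0, bottle.height / 2])
    cam_a = CameraModel.look_at(
        "cam_a", np.array([distance, 0.0, bottle.height / 2]), target, focal_px
    )
    cam_b = CameraModel.look_at(
        "cam_b", np.array([0.0, -distance, bottle.height / 2]), target, focal_px
    )
    return cam_a, cam_b
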