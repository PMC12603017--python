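"""Pinhole camera model and point-cloud primitives.

Conventions used throughout the package:

* depth rasters are in **millimeters** (0 marks an invalid pixel), the
  convention of consumer depth cameras;
* point clouds are in **meters**, camera frame: X right, Y down, Z along
  the optical axis toward the table (so a horizontal table is a plane of
  near-constant Z);
* pixel coordinates are 0-based with pixel centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class InvalidDepthError(ValueError):
    """Raised for non-positive depth where a valid depth is required."""


class BehindCameraError(ValueError):
    """Raised when projecting a point with Z <= 0."""


class ParameterError(ValueError):
    """Raised for out-of-range algorithm parameters."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics (focal lengths and principal point, in pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ParameterError("focal lengths must be positive")
        if not (0 <= self.cx < self.width) or not (0 <= self.cy < self.height):
            raise ParameterError("principal point must lie inside the raster")

    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(**{k: d[k] for k in ("fx", "fy", "cx", "cy", "width", "height")})


#: Typical intrinsics for a 640x480 consumer structured-light depth sensor.
DEFAULT_INTRINSICS = CameraIntrinsics(
    fx=615.0, fy=615.0, cx=319.5, cy=239.5, width=640, height=480
)


@dataclass
class DepthFrame:
    """A depth raster (mm) with optional RGB and a capture timestamp (s)."""

    depth: np.ndarray
    intrinsics: CameraIntrinsics
    rgb: Optional[np.ndarray] = None
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.shape != (self.intrinsics.height, self.intrinsics.width):
            raise ParameterError("depth raster shape does not match intrinsics")
        if np.any(self.depth < 0):
            raise ParameterError("depth values must be >= 0")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb, dtype=np.uint8)
            if self.rgb.shape[:2] != self.depth.shape or self.rgb.shape[2] != 3:
                raise ParameterError("rgb raster shape does not match depth")


@dataclass
class PointCloud:
    """N x 3 points (meters) with optional per-point uint8 RGB colors."""

    points: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ParameterError("colors must match points in length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, indices: np.ndarray) -> "PointCloud":
        """Subset by index array or boolean mask, keeping color correspondence."""
        indices = np.asarray(indices)
        colors = self.colors[indices] if self.colors is not None else None
        return PointCloud(self.points[indices], colors)

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        return PointCloud(transform.apply(self.points), self.colors)

    @classmethod
    def empty(cls, with_colors: bool = False) -> "PointCloud":
        colors = np.zeros((0, 3), dtype=np.uint8) if with_colors else None
        return cls(np.zeros((0, 3)), colors)


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform (rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ParameterError("transform must be 4x4")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ParameterError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ParameterError("rotation block must have determinant +1")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ParameterError("last row must be (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, r: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = np.asarray(t, dtype=np.float64).ravel()
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Pixel <-> 3D conversions
# ---------------------------------------------------------------------------

MM_PER_M = 1000.0


def deproject_pixel(u: float, v: float, d_mm: float, K: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel (u, v) with depth d (mm) to a 3D point in meters.

    X = (u - cx) * d / fx, Y = (v - cy) * d / fy, Z = d.
    """
    if d_mm <= 0:
        raise InvalidDepthError(f"depth must be positive, got {d_mm}")
    d = d_mm / MM_PER_M
    return np.array(
        [(u - K.cx) * d / K.fx, (v - K.cy) * d / K.fy, d], dtype=np.float64
    )


def project_point(p: np.ndarray, K: CameraIntrinsics) -> tuple[float, float, float]:
    """Project a 3D point (meters) to (u, v, depth in meters)."""
    x, y, z = np.asarray(p, dtype=np.float64).ravel()
    if z <= 0:
        raise BehindCameraError(f"point has non-positive Z: {z}")
    return (K.cx + K.fx * x / z, K.cy + K.fy * y / z, z)


def depth_to_cloud(frame: DepthFrame, mask: Optional[np.ndarray] = None) -> PointCloud:
    """Convert a depth frame to a point cloud, one point per valid pixel.

    ``mask`` is an optional boolean raster restricting which pixels are
    used. Pixels with depth 0 are always skipped. Point order is row-major
    pixel order; colors are copied from the frame's RGB raster when present.
    """
    K = frame.intrinsics
    valid = frame.depth > 0
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    v_idx, u_idx = np.nonzero(valid)
    d = frame.depth[v_idx, u_idx] / MM_PER_M
    x = (u_idx - K.cx) * d / K.fx
    y = (v_idx - K.cy) * d / K.fy
    points = np.column_stack([x, y, d])
    colors = frame.rgb[v_idx, u_idx] if frame.rgb is not None else None
    return PointCloud(points, colors)


# ---------------------------------------------------------------------------
# Point-cloud primitives
# ---------------------------------------------------------------------------


def crop_to_disk(
    cloud: PointCloud, center_xy: np.ndarray, radius: float, margin: float = 0.0
) -> PointCloud:
    """Keep points whose XY distance to ``center_xy`` is <= radius + margin."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    center = np.asarray(center_xy, dtype=np.float64).ravel()[:2]
    d2 = np.sum((cloud.points[:, :2] - center) ** 2, axis=1)
    return cloud.select(d2 <= (radius + margin) ** 2)


def voxel_downsample(cloud: PointCloud, voxel: float) -> PointCloud:
    """Average points within each occupied cell of a grid anchored at the origin.

    The representative of a voxel is the centroid of its member points,
    which preserves surface position better than the voxel center.
    """
    if voxel <= 0:
        raise ParameterError("voxel size must be positive")
    if len(cloud) == 0:
        return cloud.select(np.zeros(0, dtype=int))
    keys = np.floor(cloud.points / voxel).astype(np.int64)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    n_vox = len(counts)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, cloud.points)
    centroids = sums / counts[:, None]
    colors = None
    if cloud.colors is not None:
        csum = np.zeros((n_vox, 3))
        np.add.at(csum, inverse, cloud.colors.astype(np.float64))
        colors = np.clip(np.round(csum / counts[:, None]), 0, 255).astype(np.uint8)
    return PointCloud(centroids, colors)
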