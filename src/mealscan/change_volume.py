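"""Consumed-food volume between two aligned clouds.

The change surface is found by distance-threshold differencing: points of
the earlier cloud farther than a threshold from the later cloud are the
"top" of the removed material. Each top point is paired with its
XY-nearest point of the later cloud (the "bottom"), the pair difference
gives a height field above z = 0, and the volume is integrated by 2D
Delaunay triangulation with truncated-prism summation:

    V_prism = (1/6) |z1 + z2 + z3| |x1 y2 - x2 y1 + x2 y3 - x3 y2
                                    + x3 y1 - x1 y3|

i.e. mean vertex height times projected triangle area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .geometry import PointCloud, RigidTransform
from .registration import RegistrationResult, register_pair
from .segmentation import DegenerateInputError

logger = logging.getLogger(__name__)

CM3_PER_M3 = 1e6


@dataclass
class ChangeSurface:
    """Paired top / bottom / origin-corrected clouds of the changed region."""

    top: PointCloud
    bottom: PointCloud
    corrected: PointCloud


@dataclass
class TriangulatedSurface:
    vertices: np.ndarray
    triangles: np.ndarray


@dataclass
class ChangeParams:
    dist_thresh: float = 0.005  # m; change-extraction threshold
    voxel: float = 0.003  # m; downsampling for registration
    min_fitness: float = 0.5  # registration reliability gate
    seed: int = 0
    register: bool = True
    # density filter on the extracted change surface: sensor noise puts
    # scattered points past the distance threshold, and even a few of
    # them create huge spurious Delaunay triangles
    denoise: bool = True
    denoise_eps: float = 0.004  # m
    denoise_min_pts: int = 12
    # region closing: after detection, include every earlier-frame point
    # whose XY lies within this distance of a detected point, so heights
    # over the changed region are sampled unconditionally (detection
    # alone keeps only points that noise pushed past the threshold,
    # biasing the integrated height field upward)
    fill_radius: float = 0.005  # m; 0 disables


@dataclass
class VolumeResult:
    """Consumed volume (cm^3) with pipeline diagnostics."""

    volume_cm3: float
    n_changed: int
    registration: Optional[RegistrationResult]
    clamped_fraction: float
    reliable: bool
    surface: Optional[ChangeSurface] = None


def extract_changed(
    cloud_t: PointCloud, cloud_t1: PointCloud, dist_thresh: float
) -> PointCloud:
    """Points of ``cloud_t`` whose nearest neighbor in ``cloud_t1`` is
    farther than ``dist_thresh`` — the surface that disappeared between
    the two (registered) captures."""
    if len(cloud_t1) == 0:
        logger.warning("change extraction against an empty target: keeping all")
        return cloud_t.select(np.arange(len(cloud_t)))
    if len(cloud_t) == 0:
        return cloud_t
    tree = cKDTree(cloud_t1.points)
    d, _ = tree.query(cloud_t.points)
    return cloud_t.select(d > dist_thresh)


def project_bottom(top: PointCloud, target: PointCloud) -> PointCloud:
    """For each top point, the target point nearest in the XY plane.

    Gives the surface the removed material used to rest on (the later
    frame's surface directly beneath each top point).
    """
    if len(target) == 0:
        raise DegenerateInputError("cannot project onto an empty target cloud")
    tree = cKDTree(target.points[:, :2])
    _, j = tree.query(top.points[:, :2])
    return target.select(j)


def z_origin_correct(top: PointCloud, bottom: PointCloud) -> PointCloud:
    """Shift each top point so its Z is the height above its bottom pair:
    output_i = (x_i, y_i, z_i - z'_i); XY is unchanged."""
    if len(top) != len(bottom):
        raise DegenerateInputError("top and bottom clouds must be paired 1:1")
    dz = top.points[:, 2] - bottom.points[:, 2]
    pts = np.column_stack([top.points[:, 0], top.points[:, 1], dz])
    return PointCloud(pts, top.colors)


def delaunay_xy(points: PointCloud) -> TriangulatedSurface:
    """2D Delaunay triangulation of the XY projection, lifting vertex Z.

    Degenerate (zero-XY-area) triangles are dropped. Raises
    ``DegenerateInputError`` for fewer than 3 points or collinear input.
    """
    pts = points.points
    if len(pts) < 3:
        raise DegenerateInputError("triangulation needs at least 3 points")
    try:
        tri = Delaunay(pts[:, :2])
    except QhullError as exc:
        raise DegenerateInputError(f"degenerate XY configuration: {exc}") from exc
    simplices = tri.simplices
    a, b, c = (pts[simplices[:, k], :2] for k in range(3))
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    keep = area2 > 1e-14
    if not np.any(keep):
        raise DegenerateInputError("all triangles degenerate (collinear points)")
    return TriangulatedSurface(vertices=pts, triangles=simplices[keep])


def prism_volume(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Volume of the truncated triangular prism between triangle (a, b, c)
    and the plane z = 0."""
    x1, y1, z1 = a
    x2, y2, z2 = b
    x3, y3, z3 = c
    return (
        abs(z1 + z2 + z3)
        * abs(x1 * y2 - x2 * y1 + x2 * y3 - x3 * y2 + x3 * y1 - x1 * y3)
        / 6.0
    )


def _prism_volumes(surface: TriangulatedSurface) -> np.ndarray:
    v = surface.vertices
    t = surface.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    zsum = np.abs(a[:, 2] + b[:, 2] + c[:, 2])
    cross = np.abs(
        a[:, 0] * b[:, 1]
        - b[:, 0] * a[:, 1]
        + b[:, 0] * c[:, 1]
        - c[:, 0] * b[:, 1]
        + c[:, 0] * a[:, 1]
        - a[:, 0] * c[:, 1]
    )
    return zsum * cross / 6.0


def surface_volume(points: PointCloud) -> float:
    """Integrate a height field (Z = height above z = 0, meters) to a
    volume in cm^3 by Delaunay meshing and prism summation."""
    surface = delaunay_xy(points)
    return float(_prism_volumes(surface).sum() * CM3_PER_M3)


def consumed_volume(
    frame_t: PointCloud,
    frame_t1: PointCloud,
    params: Optional[ChangeParams] = None,
) -> VolumeResult:
    """Volume of food removed between two per-plate captures.

    Chain: register the later cloud onto the earlier one, extract the
    changed surface from the earlier cloud, pair it with the later
    surface beneath it, convert to heights, clamp noise-induced negative
    heights to zero (consumed volume cannot be negative; the clamped
    fraction is reported), then mesh and integrate.

    In the camera frame Z points down toward the table, so raw top-bottom
    height differences of removed food come out negative; the height field
    is sign-normalized before clamping.
    """
    params = params or ChangeParams()
    registration: Optional[RegistrationResult] = None
    aligned_t1 = frame_t1
    reliable = True
    if params.register and len(frame_t) >= 3 and len(frame_t1) >= 3:
        registration = register_pair(
            frame_t1, frame_t, voxel=params.voxel, seed=params.seed
        )
        if registration.success and registration.fitness >= params.min_fitness:
            aligned_t1 = frame_t1.transformed(registration.transform)
        else:
            logger.warning(
                "unreliable registration (fitness %.3f); using raw frames",
                registration.fitness if registration else 0.0,
            )
            reliable = False

    top = extract_changed(frame_t, aligned_t1, params.dist_thresh)
    if params.denoise and len(top) >= 3:
        from .segmentation import dbscan_cluster  # deferred: avoid import cycle

        labels = dbscan_cluster(top, params.denoise_eps, params.denoise_min_pts)
        top = top.select(labels.labels >= 0)
    if params.fill_radius > 0 and len(top) >= 3:
        tree_xy = cKDTree(top.points[:, :2])
        d_xy, _ = tree_xy.query(frame_t.points[:, :2])
        top = frame_t.select(d_xy <= params.fill_radius)
    if len(top) < 3:
        return VolumeResult(0.0, len(top), registration, 0.0, reliable, None)
    bottom = project_bottom(top, aligned_t1)
    corrected = z_origin_correct(top, bottom)
    heights = corrected.points[:, 2]
    if heights.sum() < 0:  # camera-frame orientation: flip to heights-up
        heights = -heights
    clamped = heights < 0
    clamped_fraction = float(clamped.mean())
    heights = np.maximum(heights, 0.0)
    corrected = PointCloud(
        np.column_stack([corrected.points[:, 0], corrected.points[:, 1], heights]),
        corrected.colors,
    )
    try:
        volume = surface_volume(corrected)
    except DegenerateInputError:
        volume = 0.0
    return VolumeResult(
        volume_cm3=max(volume, 0.0),
        n_changed=len(top),
        registration=registration,
        clamped_fraction=clamped_fraction,
        reliable=reliable,
        surface=ChangeSurface(top=top, bottom=bottom, corrected=corrected),
    )
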