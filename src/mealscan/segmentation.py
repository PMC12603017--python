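"""Table / plate / food separation for a cropped per-plate point cloud.

The pipeline: a RANSAC plane pass removes the dominant flat surface, a
second pass removes the remaining flat surface (plate interior vs. table
ring, whichever was not caught first), DBSCAN clusters what is left, a
per-cluster RMS-distance filter drops far-away clutter, and an annulus
rule reassigns plate-rim clusters to the plate. What survives is food.

A second plane pass is essential for an emptied plate: its exposed flat
bottom would otherwise be clustered and misread as food.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import DBSCAN

from .geometry import CameraIntrinsics, ParameterError, PointCloud, project_point


class DegenerateInputError(ValueError):
    """Raised when a model cannot be fitted (too few / collinear points)."""


class MissingColorError(ValueError):
    """Raised when an operation needs per-point colors and none exist."""


@dataclass
class PlaneModel:
    """Plane normal·p + offset = 0 with unit normal, plus its inliers."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray

    def distances(self, points: np.ndarray) -> np.ndarray:
        return np.abs(points @ self.normal + self.offset)


@dataclass
class ClusterLabels:
    """Per-point labels: -1 = noise, 0..k-1 = clusters (contiguous ids)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if np.any(self.labels >= 0) else 0

    def indices_of(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


@dataclass
class SceneSegmentation:
    """Disjoint table / plate / food subsets of one cropped cloud."""

    table: PointCloud
    plate: PointCloud
    food: PointCloud
    food_labels: Optional[ClusterLabels] = None


@dataclass
class SegmentationParams:
    plane_dist_thresh: float = 0.003  # m
    ransac_iters: int = 1000
    dbscan_eps: float = 0.008  # m
    dbscan_min_pts: int = 10
    rms_max_dist: Optional[float] = None  # m; default: plate radius
    min_plane_points: int = 200
    rim_annulus_fraction: float = 0.8  # clusters mostly beyond this radius -> plate
    seed: int = 0


def _fit_plane_lsq(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through points (SVD on centered coords)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    normal = vt[-1]
    return normal, float(-normal @ centroid)


def fit_plane_ransac(
    cloud: PointCloud,
    dist_thresh: float = 0.003,
    n_iters: int = 1000,
    seed: int = 0,
) -> PlaneModel:
    """Robust plane fit: best of ``n_iters`` random 3-point candidates,
    refined by least squares over the winning candidate's inliers.

    Deterministic for a fixed seed. Raises ``DegenerateInputError`` when
    fewer than 3 points are given or all samples are collinear.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise DegenerateInputError("plane fit needs at least 3 points")
    rng = np.random.default_rng(seed)
    best_count = -1
    best_normal = None
    best_offset = 0.0
    samples = rng.integers(0, n, size=(n_iters, 3))
    for a, b, c in samples:
        v1 = pts[b] - pts[a]
        v2 = pts[c] - pts[a]
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        offset = -normal @ pts[a]
        count = int(np.count_nonzero(np.abs(pts @ normal + offset) <= dist_thresh))
        if count > best_count:
            best_count = count
            best_normal, best_offset = normal, offset
    if best_normal is None:
        raise DegenerateInputError("all RANSAC samples were collinear")
    # least-squares refinement over the consensus set, then recompute inliers
    inliers = np.nonzero(np.abs(pts @ best_normal + best_offset) <= dist_thresh)[0]
    if len(inliers) >= 3:
        normal, offset = _fit_plane_lsq(pts[inliers])
        refined = np.nonzero(np.abs(pts @ normal + offset) <= dist_thresh)[0]
        if len(refined) >= len(inliers):
            best_normal, best_offset, inliers = normal, offset, refined
    return PlaneModel(best_normal, best_offset, inliers)


def remove_plane(cloud: PointCloud, plane: PlaneModel) -> PointCloud:
    """Drop the plane's inlier points, keeping color correspondence."""
    keep = np.ones(len(cloud), dtype=bool)
    keep[plane.inlier_indices] = False
    return cloud.select(keep)


def dbscan_cluster(cloud: PointCloud, eps: float, min_pts: int) -> ClusterLabels:
    """Density-reachability clustering; unreachable sparse points get -1."""
    if eps <= 0:
        raise ParameterError("eps must be positive")
    if min_pts < 1:
        raise ParameterError("min_pts must be >= 1")
    if len(cloud) == 0:
        return ClusterLabels(np.zeros(0, dtype=np.int64))
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(cloud.points).labels_
    return ClusterLabels(labels)


def filter_clusters_by_rms(
    cloud: PointCloud, labels: ClusterLabels, max_dist: float
) -> ClusterLabels:
    """Relabel as noise any cluster whose RMS point distance to the global
    cloud centroid exceeds ``max_dist``.

    The RMS distance of a cluster is sqrt(mean of squared Euclidean
    distances of its points to the centroid of the whole cloud), so a
    compact nearby cluster passes while far clutter is discarded.
    """
    out = labels.labels.copy()
    if len(cloud) == 0:
        return ClusterLabels(out)
    centroid = cloud.points.mean(axis=0)
    kept = 0
    remap: dict[int, int] = {}
    for k in range(labels.n_clusters):
        idx = labels.indices_of(k)
        rms = np.sqrt(np.mean(np.sum((cloud.points[idx] - centroid) ** 2, axis=1)))
        if rms > max_dist:
            out[idx] = -1
        else:
            remap[k] = kept
            kept += 1
    # keep cluster ids contiguous after removals
    for k, new in remap.items():
        if new != k:
            out[labels.labels == k] = new
    return ClusterLabels(out)


def _second_plane(
    cloud: PointCloud, params: SegmentationParams, reference_normal: np.ndarray
) -> Optional[PlaneModel]:
    """Fit a second flat surface roughly parallel to the first plane.

    Restricting the orientation prevents a tilted plane from slicing a
    band out of a curved food mound.
    """
    if len(cloud) < max(3, params.min_plane_points):
        return None
    try:
        plane = fit_plane_ransac(
            cloud, params.plane_dist_thresh, params.ransac_iters, params.seed + 1
        )
    except DegenerateInputError:
        return None
    cos = abs(float(plane.normal @ reference_normal))
    if cos < np.cos(np.radians(15.0)):
        return None
    if len(plane.inlier_indices) < params.min_plane_points:
        return None
    return plane


def segment_scene(
    cloud: PointCloud, params: Optional[SegmentationParams] = None
) -> SceneSegmentation:
    """Split a cropped per-plate cloud into table, plate, and food parts.

    Two plane passes catch the two flat surfaces present in a plate crop
    (table and plate interior; order depends on which dominates the crop).
    The deeper plane (larger mean Z, i.e. farther from the camera) is
    reported as the table. Remaining points are DBSCAN-clustered, far
    clusters are dropped by the RMS rule, and clusters that sit mostly in
    the outer annulus of the plate footprint (the raised rim) are counted
    as plate rather than food.
    """
    params = params or SegmentationParams()
    n = len(cloud)
    plane1 = fit_plane_ransac(
        cloud, params.plane_dist_thresh, params.ransac_iters, params.seed
    )
    idx_all = np.arange(n)
    plane1_idx = plane1.inlier_indices
    rest = remove_plane(cloud, plane1)
    rest_idx = np.setdiff1d(idx_all, plane1_idx, assume_unique=False)

    plane2 = _second_plane(rest, params, plane1.normal)
    if plane2 is not None:
        plane2_idx = rest_idx[plane2.inlier_indices]
        rest = remove_plane(rest, plane2)
        rest_idx = np.setdiff1d(rest_idx, plane2_idx)
    else:
        plane2_idx = np.zeros(0, dtype=int)

    # the farther plane (larger mean depth) is the table
    if len(plane2_idx):
        z1 = cloud.points[plane1_idx, 2].mean()
        z2 = cloud.points[plane2_idx, 2].mean()
        table_idx, plate_idx = (
            (plane1_idx, plane2_idx) if z1 >= z2 else (plane2_idx, plane1_idx)
        )
    else:
        table_idx, plate_idx = plane1_idx, np.zeros(0, dtype=int)

    labels = dbscan_cluster(rest, params.dbscan_eps, params.dbscan_min_pts)
    plate_pts = cloud.points[plate_idx]
    ref_pts = plate_pts if len(plate_pts) else cloud.points
    center_xy = ref_pts[:, :2].mean(axis=0)
    radial = np.linalg.norm(ref_pts[:, :2] - center_xy, axis=1)
    plate_radius = float(np.quantile(radial, 0.99)) if len(radial) else 0.1
    max_dist = params.rms_max_dist if params.rms_max_dist is not None else plate_radius
    labels = filter_clusters_by_rms(rest, labels, max_dist)

    # rim clusters: mostly in the outer annulus of the plate footprint
    food_mask = np.zeros(len(rest), dtype=bool)
    rim_mask = np.zeros(len(rest), dtype=bool)
    for k in range(labels.n_clusters):
        idx = labels.indices_of(k)
        r = np.linalg.norm(rest.points[idx, :2] - center_xy, axis=1)
        if np.mean(r > params.rim_annulus_fraction * plate_radius) >= 0.8:
            rim_mask[idx] = True
        else:
            food_mask[idx] = True

    food_idx = rest_idx[food_mask]
    plate_idx = np.sort(np.concatenate([plate_idx, rest_idx[rim_mask]]))
    food_labels_arr = labels.labels[food_mask]
    # re-number food cluster ids contiguously
    uniq = np.unique(food_labels_arr[food_labels_arr >= 0])
    renum = {old: new for new, old in enumerate(uniq)}
    food_labels_arr = np.array(
        [renum.get(v, -1) for v in food_labels_arr], dtype=np.int64
    )
    return SceneSegmentation(
        table=cloud.select(table_idx),
        plate=cloud.select(plate_idx),
        food=cloud.select(food_idx),
        food_labels=ClusterLabels(food_labels_arr),
    )


def detect_plates(
    cloud: PointCloud,
    params: Optional[SegmentationParams] = None,
    min_points: int = 500,
) -> list[tuple[np.ndarray, float]]:
    """Locate plates on a full-table cloud: remove the table plane, cluster
    the remainder, and report (center XY, radius) per sizable cluster.

    Radius is the 99th percentile of radial point distance, robust to a
    few stray points. Results are sorted by cluster size, largest first.
    """
    params = params or SegmentationParams()
    plane = fit_plane_ransac(
        cloud, params.plane_dist_thresh, params.ransac_iters, params.seed
    )
    rest = remove_plane(cloud, plane)
    labels = dbscan_cluster(rest, params.dbscan_eps * 2, params.dbscan_min_pts)
    plates: list[tuple[int, np.ndarray, float]] = []
    for k in range(labels.n_clusters):
        idx = labels.indices_of(k)
        if len(idx) < min_points:
            continue
        xy = rest.points[idx, :2]
        center = xy.mean(axis=0)
        radius = float(np.quantile(np.linalg.norm(xy - center, axis=1), 0.99))
        plates.append((len(idx), center, radius))
    plates.sort(key=lambda t: -t[0])
    return [(c, r) for _, c, r in plates]


def render_foreground_image(
    food: PointCloud, K: CameraIntrinsics
) -> tuple[np.ndarray, np.ndarray]:
    """Compress a colored food cloud back to a 2D image free of background.

    Each point is projected through the pinhole model; when several points
    land on a pixel the nearest (smallest depth) wins. Returns the RGB
    raster (uncovered pixels black) and a boolean validity mask.
    """
    if not food.has_colors:
        raise MissingColorError("foreground rendering requires per-point colors")
    rgb = np.zeros((K.height, K.width, 3), dtype=np.uint8)
    valid = np.zeros((K.height, K.width), dtype=bool)
    if len(food) == 0:
        return rgb, valid
    pts = food.points
    if np.any(pts[:, 2] <= 0):
        raise ParameterError("all food points must be in front of the camera")
    u = np.round(K.cx + K.fx * pts[:, 0] / pts[:, 2]).astype(int)
    v = np.round(K.cy + K.fy * pts[:, 1] / pts[:, 2]).astype(int)
    ok = (u >= 0) & (u < K.width) & (v >= 0) & (v < K.height)
    u, v, z = u[ok], v[ok], pts[ok, 2]
    colors = food.colors[ok]
    # nearest-depth wins: process points sorted far-to-near so closer
    # points overwrite farther ones
    order = np.argsort(-z)
    rgb[v[order], u[order]] = colors[order]
    valid[v[order], u[order]] = True
    return rgb, valid
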