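"""Rigid alignment of consecutive frame clouds.

The chain is the classic coarse-to-fine one: voxel downsampling, surface
normals by local PCA, 33-bin Fast Point Feature Histograms, mutual-nearest
feature matching feeding a RANSAC over 3-correspondence samples (with
edge-length compatibility pruning), and finally point-to-point ICP
refinement. Point-to-point (rather than point-to-plane) ICP is used
because tabletop scenes are shallow and per-point normal estimates on
near-planar regions are noisy.

All randomness is controlled by explicit seeds; results are deterministic
for fixed inputs and seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """Per-point FPFH descriptors (N x 33) aligned with a cloud's points."""

    descriptors: np.ndarray

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        if self.descriptors.ndim != 2 or self.descriptors.shape[1] != 33:
            raise ValueError("FPFH descriptors must be N x 33")

    def __len__(self) -> int:
        return len(self.descriptors)


@dataclass
class RegistrationResult:
    """A rigid transform with quality metrics.

    ``fitness`` is the fraction of source points that found a target
    correspondence within the evaluation threshold; ``rmse`` is the RMS
    residual (m) over those correspondences.
    """

    transform: RigidTransform
    fitness: float
    rmse: float
    converged: bool = True

    @property
    def success(self) -> bool:
        return self.converged and self.fitness > 0.0


def estimate_normals(
    points: np.ndarray,
    radius: float,
    viewpoint: np.ndarray = np.zeros(3),
) -> np.ndarray:
    """Per-point unit normals from PCA over all neighbors within
    ``radius``, oriented toward ``viewpoint`` (default: the camera at the
    origin). Points with fewer than 3 neighbors get a default normal
    pointing back at the viewpoint.

    The neighbor set is taken whole (no nearest-k truncation) so it is
    invariant under rigid motion of the cloud.
    """
    viewpoint = np.asarray(viewpoint, dtype=np.float64)
    n = len(points)
    normals = np.zeros((n, 3))
    tree = cKDTree(points)
    neighbor_lists = tree.query_ball_point(points, radius)
    for i, idx in enumerate(neighbor_lists):
        nb = points[idx]
        if len(nb) < 3:
            normals[i] = (0.0, 0.0, -1.0)
            continue
        cov = np.cov(nb.T)
        w, v = np.linalg.eigh(cov)
        normals[i] = v[:, 0]
    # orient toward the viewpoint: n . (p - viewpoint) < 0
    flip = np.einsum("ij,ij->i", normals, points - viewpoint) > 0
    normals[flip] *= -1.0
    return normals


def _pair_features(
    p_s: np.ndarray, n_s: np.ndarray, p_t: np.ndarray, n_t: np.ndarray
) -> np.ndarray:
    """Darboux-frame angular features (alpha, phi, theta) for point pairs."""
    d = p_t - p_s
    dist = np.linalg.norm(d, axis=1)
    dist = np.where(dist < 1e-12, 1.0, dist)
    d = d / dist[:, None]
    u = n_s
    v = np.cross(d, u)
    vnorm = np.linalg.norm(v, axis=1)
    vnorm = np.where(vnorm < 1e-12, 1.0, vnorm)
    v = v / vnorm[:, None]
    w = np.cross(u, v)
    alpha = np.einsum("ij,ij->i", v, n_t)
    phi = np.einsum("ij,ij->i", u, d)
    theta = np.arctan2(np.einsum("ij,ij->i", w, n_t), np.einsum("ij,ij->i", u, n_t))
    return np.column_stack([alpha, phi, theta])


_N_BINS = 11


def _spfh(points: np.ndarray, normals: np.ndarray, radius: float) -> np.ndarray:
    """Simplified point feature histograms (3 x 11 bins, row-normalized)."""
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    hist = np.zeros((n, 3 * _N_BINS))
    if len(pairs):
        # directed pairs in both directions: each point sees its neighbors
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        feats = _pair_features(points[src], normals[src], points[dst], normals[dst])
        edges = [
            np.linspace(-1.0, 1.0, _N_BINS + 1),
            np.linspace(-1.0, 1.0, _N_BINS + 1),
            np.linspace(-np.pi, np.pi, _N_BINS + 1),
        ]
        for f in range(3):
            bins = np.clip(
                np.digitize(feats[:, f], edges[f]) - 1, 0, _N_BINS - 1
            )
            np.add.at(hist, (src, f * _N_BINS + bins), 1.0)
    sums = hist.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return hist / sums


def compute_fpfh(
    cloud: PointCloud,
    normal_radius: float,
    feature_radius: float,
    viewpoint: np.ndarray = np.zeros(3),
) -> FeatureSet:
    """33-bin FPFH descriptors for every point of a (downsampled) cloud.

    FPFH(p) = SPFH(p) + mean over neighbors q of SPFH(q) / ||p - q||,
    normalized per point. Points with no neighbor inside
    ``feature_radius`` keep a zero descriptor (logged), which simply never
    matches anything downstream.
    """
    if normal_radius <= 0 or feature_radius <= 0:
        raise ValueError("radii must be positive")
    points = cloud.points
    n = len(points)
    if n == 0:
        return FeatureSet(np.zeros((0, 33)))
    normals = estimate_normals(points, normal_radius, viewpoint=viewpoint)
    spfh = _spfh(points, normals, feature_radius)
    tree = cKDTree(points)
    pairs = tree.query_pairs(feature_radius, output_type="ndarray")
    if len(pairs):
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        dist = np.linalg.norm(points[src] - points[dst], axis=1)
        w = 1.0 / np.maximum(dist, 1e-9)
        weights = sparse.coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
        counts = np.asarray((weights > 0).sum(axis=1)).ravel()
        neighbor_term = np.asarray(weights @ spfh)
        nz = counts > 0
        fpfh = spfh.copy()
        fpfh[nz] += neighbor_term[nz] / counts[nz, None]
    else:
        fpfh = spfh.copy()
    isolated = ~np.any(fpfh > 0, axis=1)
    if np.any(isolated):
        logger.info("%d isolated points got zero FPFH descriptors", isolated.sum())
        fpfh[isolated] = 0.0
    sums = fpfh.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return FeatureSet(fpfh / sums)


def best_fit_transform(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired source -> target
    points (Kabsch / Umeyama without scaling)."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (source - mu_s).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    t = mu_t - r @ mu_s
    return RigidTransform.from_rotation_translation(r, t)


def _mutual_matches(fs: np.ndarray, ft: np.ndarray) -> np.ndarray:
    """Indices (i, j) of mutually-nearest descriptor pairs."""
    tree_t = cKDTree(ft)
    tree_s = cKDTree(fs)
    _, fwd = tree_t.query(fs)  # source i -> target fwd[i]
    _, back = tree_s.query(ft)  # target j -> source back[j]
    i = np.arange(len(fs))
    mutual = back[fwd] == i
    return np.column_stack([i[mutual], fwd[mutual]])


def _evaluate(
    source: np.ndarray, target_tree: cKDTree, transform: RigidTransform, thresh: float
) -> tuple[float, float]:
    moved = transform.apply(source)
    d, _ = target_tree.query(moved, distance_upper_bound=thresh)
    hit = np.isfinite(d)
    if not np.any(hit):
        return 0.0, 0.0
    return float(hit.mean()), float(np.sqrt(np.mean(d[hit] ** 2)))


def global_register(
    source: PointCloud,
    target: PointCloud,
    fs: FeatureSet,
    ft: FeatureSet,
    dist_thresh: float,
    seed: int = 0,
    n_iters: int = 4000,
    edge_similarity: float = 0.9,
) -> RegistrationResult:
    """Feature-based RANSAC global registration.

    Mutual-nearest FPFH matches propose correspondences; random
    3-correspondence samples whose intra-set edge lengths agree (ratio >
    ``edge_similarity``) yield candidate rigid transforms, scored by
    correspondence inliers within ``dist_thresh``. The best candidate is
    refined by a least-squares fit over its inliers. Returns a failure
    result (identity, fitness 0) when no valid sample is found.
    """
    if len(source) < 3 or len(target) < 3:
        return RegistrationResult(RigidTransform.identity(), 0.0, 0.0, converged=False)
    matches = _mutual_matches(fs.descriptors, ft.descriptors)
    target_tree = cKDTree(target.points)
    if len(matches) < 3:
        logger.warning("global registration: fewer than 3 feature matches")
        return RegistrationResult(RigidTransform.identity(), 0.0, 0.0, converged=False)
    ps = source.points[matches[:, 0]]
    pt = target.points[matches[:, 1]]
    rng = np.random.default_rng(seed)
    best_count = 0
    best_transform = None
    triples = rng.integers(0, len(matches), size=(n_iters, 3))
    for tri in triples:
        if len(set(tri)) < 3:
            continue
        a = ps[tri]
        b = pt[tri]
        ok = True
        for i, j in ((0, 1), (1, 2), (0, 2)):
            ds = np.linalg.norm(a[i] - a[j])
            dt = np.linalg.norm(b[i] - b[j])
            m = max(ds, dt)
            if m < 1e-9 or min(ds, dt) / m < edge_similarity:
                ok = False
                break
        if not ok:
            continue
        cand = best_fit_transform(a, b)
        resid = np.linalg.norm(cand.apply(ps) - pt, axis=1)
        count = int(np.count_nonzero(resid <= dist_thresh))
        if count > best_count:
            best_count = count
            best_transform = cand
    if best_transform is None or best_count < 3:
        logger.warning("global registration found no consensus sample")
        return RegistrationResult(RigidTransform.identity(), 0.0, 0.0, converged=False)
    resid = np.linalg.norm(best_transform.apply(ps) - pt, axis=1)
    inliers = resid <= dist_thresh
    refined = best_fit_transform(ps[inliers], pt[inliers])
    fitness, rmse = _evaluate(source.points, target_tree, refined, dist_thresh)
    return RegistrationResult(refined, fitness, rmse)


def refine_icp(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform,
    max_corr: float,
    max_iters: int = 50,
    tol: float = 1e-6,
) -> RegistrationResult:
    """Point-to-point ICP from an initial transform.

    Alternates nearest-neighbor correspondence (rejecting pairs farther
    than ``max_corr``) with a least-squares rigid update. An iteration
    that would increase the RMSE is rejected and iteration stops, so the
    reported RMSE sequence is non-increasing. Returns a failure result if
    no correspondences exist at the initialization.
    """
    src = source.points
    target_tree = cKDTree(target.points)
    transform = init
    prev_rmse = np.inf
    fitness = 0.0
    for _ in range(max_iters):
        moved = transform.apply(src)
        d, j = target_tree.query(moved, distance_upper_bound=max_corr)
        hit = np.isfinite(d)
        if not np.any(hit):
            logger.warning("ICP: empty correspondence set")
            return RegistrationResult(init, 0.0, 0.0, converged=False)
        rmse = float(np.sqrt(np.mean(d[hit] ** 2)))
        fitness = float(hit.mean())
        if rmse > prev_rmse:
            break
        if prev_rmse - rmse < tol:
            prev_rmse = rmse
            break
        prev_rmse = rmse
        update = best_fit_transform(moved[hit], target.points[j[hit]])
        transform = update.compose(transform)
    rmse = 0.0 if not np.isfinite(prev_rmse) else prev_rmse
    return RegistrationResult(transform, fitness, rmse)


def register_pair(
    source: PointCloud,
    target: PointCloud,
    voxel: float = 0.003,
    seed: int = 0,
    identity_fitness: float = 0.8,
    min_global_fitness: float = 0.3,
) -> RegistrationResult:
    """Full coarse-to-fine alignment of ``source`` onto ``target``.

    Both clouds are voxel-downsampled. Because consecutive captures from
    a fixed camera are already nearly aligned, ICP from the identity is
    tried first; it is accepted when its fitness reaches
    ``identity_fitness``. (Besides being cheaper, this avoids the failure
    mode where feature-based global registration of a rotationally
    near-symmetric tabletop snaps to a wrong symmetry.) Otherwise FPFH +
    RANSAC proposes a coarse transform that ICP refines, with an identity
    initialization as last resort when the global fitness is poor.
    """
    from .geometry import voxel_downsample  # local import to avoid cycle noise

    ds_s = voxel_downsample(source, voxel)
    ds_t = voxel_downsample(target, voxel)
    direct = refine_icp(ds_s, ds_t, RigidTransform.identity(), max_corr=2 * voxel)
    if direct.success and direct.fitness >= identity_fitness:
        return direct
    fs = compute_fpfh(ds_s, normal_radius=2 * voxel, feature_radius=5 * voxel)
    ft = compute_fpfh(ds_t, normal_radius=2 * voxel, feature_radius=5 * voxel)
    coarse = global_register(ds_s, ds_t, fs, ft, dist_thresh=1.5 * voxel, seed=seed)
    init = (
        coarse.transform
        if coarse.fitness >= min_global_fitness
        else RigidTransform.identity()
    )
    refined = refine_icp(ds_s, ds_t, init, max_corr=2 * voxel)
    if direct.success and (not refined.success or direct.fitness > refined.fitness):
        return direct
    return refined
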