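"""Parametric synthetic dining scenes with analytic ground truth.

Emulates the study conditions of the measurement setup: a depth camera
mounted nadir about half a meter above a flat table, viewing ceramic
plates bearing food mounds, with bites removed between one-minute
samples. Food is modeled as spherical caps — a realistic mound profile
with a closed-form volume V = (π·h/6)(3a² + h²) — and plates as a flat
disk 8 mm above the table with a raised rim ring, which gives the
registration stage stable exterior features to lock onto. (The
plate-to-table separation must exceed twice the plane-inlier threshold
used in segmentation, or the two flat surfaces cannot be told apart;
8 mm is typical of a ceramic dinner plate interior.)

Bites shrink a cap along its own sphere (reducing height and footprint
together), so every intermediate state stays a spherical cap and the
removed volume is known exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import CameraIntrinsics, DepthFrame, ParameterError, MM_PER_M

PLATE_THICKNESS = 0.008  # m; plate surface above the table
RIM_WIDTH = 0.008  # m; width of the raised rim annulus

LABEL_TABLE = 0
LABEL_PLATE = 1
LABEL_RIM = 2
LABEL_MOUND_BASE = 3  # mound i renders as LABEL_MOUND_BASE + i

TABLE_COLOR = (120, 110, 100)
PLATE_COLOR = (235, 235, 230)
RIM_COLOR = (210, 210, 205)


@dataclass
class PlateSpec:
    center: tuple[float, float]  # table XY, m
    radius: float  # m
    rim_height: float = 0.01  # m above the plate surface
    color: tuple[int, int, int] = PLATE_COLOR


@dataclass
class MoundSpec:
    mound_id: str
    plate: int
    center: tuple[float, float]  # XY, m
    a: float  # cap base radius, m
    h: float  # cap height, m
    color: tuple[int, int, int] = (60, 160, 60)

    @property
    def sphere_radius(self) -> float:
        return (self.a**2 + self.h**2) / (2.0 * self.h)


@dataclass
class SceneSpec:
    """Camera-frame scene: Z is depth, the table sits at z = table_depth."""

    table_depth: float = 0.5  # m; 0.45-0.55 matches the mounting height
    plates: list[PlateSpec] = field(default_factory=list)
    mounds: list[MoundSpec] = field(default_factory=list)
    noise_sigma: float = 0.001  # m, Gaussian depth noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.table_depth <= 0:
            raise ParameterError("camera must be above the table (table_depth > 0)")
        for m in self.mounds:
            if m.a <= 0 or m.h <= 0:
                raise ParameterError("mound cap parameters must be positive")
            plate = self.plates[m.plate]
            off = np.hypot(
                m.center[0] - plate.center[0], m.center[1] - plate.center[1]
            )
            if off + m.a > plate.radius:
                raise ParameterError("mound must lie within its plate")

    def mound(self, mound_id: str) -> MoundSpec:
        for m in self.mounds:
            if m.mound_id == mound_id:
                return m
        raise KeyError(f"unknown mound: {mound_id!r}")


def analytic_mound_volume(a: float, h: float) -> float:
    """Spherical-cap volume (π·h/6)(3a² + h²), in cm³."""
    if a <= 0 or h <= 0:
        raise ParameterError("cap parameters must be positive")
    return (np.pi * h / 6.0) * (3.0 * a**2 + h**2) * 1e6


def _cap_volume_m3(h: float, sphere_radius: float) -> float:
    """Cap volume from height and sphere radius: π h² (R − h/3)."""
    return np.pi * h**2 * (sphere_radius - h / 3.0)


def render_depth(
    spec: SceneSpec,
    K: CameraIntrinsics,
    timestamp: float = 0.0,
    seed: Optional[int] = None,
    return_labels: bool = False,
):
    """Ray-cast the scene to a depth frame (mm) with per-surface RGB.

    For every pixel the nearest valid surface along its ray wins (the
    camera looks down, so the z-minimum handles occlusion). Gaussian
    depth noise of ``spec.noise_sigma`` is added, clamped at zero.
    Deterministic for a fixed seed. With ``return_labels`` the exact
    per-pixel surface labels (before noise) are returned alongside.
    """
    u = np.arange(K.width)
    v = np.arange(K.height)
    uu, vv = np.meshgrid(u, v)
    dx = (uu - K.cx) / K.fx
    dy = (vv - K.cy) / K.fy

    z_table = spec.table_depth
    depth = np.full((K.height, K.width), z_table)
    labels = np.full((K.height, K.width), LABEL_TABLE, dtype=np.int32)

    def consider(z_cand: np.ndarray, valid: np.ndarray, label: int) -> None:
        better = valid & (z_cand < depth)
        depth[better] = z_cand[better]
        labels[better] = label

    for plate in spec.plates:
        z_plate = z_table - PLATE_THICKNESS
        xy_r = np.hypot(dx * z_plate - plate.center[0], dy * z_plate - plate.center[1])
        consider(np.full_like(depth, z_plate), xy_r <= plate.radius, LABEL_PLATE)
        z_rim = z_plate - plate.rim_height
        xy_rim = np.hypot(dx * z_rim - plate.center[0], dy * z_rim - plate.center[1])
        rim_valid = (xy_rim <= plate.radius) & (xy_rim >= plate.radius - RIM_WIDTH)
        consider(np.full_like(depth, z_rim), rim_valid, LABEL_RIM)

    for i, m in enumerate(spec.mounds):
        plate = spec.plates[m.plate]
        z_plate = z_table - PLATE_THICKNESS
        R = m.sphere_radius
        c = np.array([m.center[0], m.center[1], z_plate - m.h + R])
        # ray p(t) = t*(dx, dy, 1); |p - c|^2 = R^2
        A = dx**2 + dy**2 + 1.0
        B = -2.0 * (dx * c[0] + dy * c[1] + c[2])
        Cq = float(c @ c - R**2)
        disc = B**2 - 4.0 * A * Cq
        ok = disc >= 0
        t = np.where(ok, (-B - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * A), np.inf)
        valid = ok & (t > 0) & (t <= z_plate)  # upper cap only
        consider(t, valid, LABEL_MOUND_BASE + i)

    rgb = np.zeros((K.height, K.width, 3), dtype=np.uint8)
    rgb[labels == LABEL_TABLE] = TABLE_COLOR
    for plate in spec.plates:  # all plates share label ids; color per spec
        rgb[labels == LABEL_PLATE] = plate.color
        rgb[labels == LABEL_RIM] = RIM_COLOR
    for i, m in enumerate(spec.mounds):
        rgb[labels == LABEL_MOUND_BASE + i] = m.color

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    depth_mm = depth * MM_PER_M
    if spec.noise_sigma > 0:
        depth_mm = depth_mm + rng.normal(
            0.0, spec.noise_sigma * MM_PER_M, size=depth_mm.shape
        )
    depth_mm = np.maximum(depth_mm, 0.0)
    frame = DepthFrame(depth_mm, K, rgb=rgb, timestamp=timestamp)
    if return_labels:
        return frame, labels
    return frame


def take_bite(
    spec: SceneSpec, mound_id: str, fraction: float
) -> tuple[SceneSpec, float]:
    """Remove ``fraction`` of a mound's current volume; return the new
    scene and the exactly-known removed volume (cm³).

    The cap is shrunk along its own sphere: height is reduced and the
    base radius recomputed so the shape stays a spherical cap of the same
    curvature.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("bite fraction must be in (0, 1]")
    mound = spec.mound(mound_id)  # KeyError if unknown / already eaten
    new_spec = copy.deepcopy(spec)
    R = mound.sphere_radius
    v0 = _cap_volume_m3(mound.h, R)
    if fraction == 1.0:
        new_spec.mounds = [m for m in new_spec.mounds if m.mound_id != mound_id]
        return new_spec, v0 * 1e6
    target = (1.0 - fraction) * v0
    h_new = brentq(lambda h: _cap_volume_m3(h, R) - target, 1e-9, mound.h)
    a_new = float(np.sqrt(h_new * (2.0 * R - h_new)))
    for m in new_spec.mounds:
        if m.mound_id == mound_id:
            m.h = float(h_new)
            m.a = a_new
    removed = (v0 - _cap_volume_m3(h_new, R)) * 1e6
    return new_spec, removed


@dataclass
class GroundTruth:
    """Analytic bookkeeping for a simulated meal."""

    interval_removed_cm3: list[float]
    interval_plate: list[int]
    frame_totals_cm3: list[float]  # total food volume present per frame
    timestamps: list[float]  # one per frame, seconds


def scene_food_volume(spec: SceneSpec) -> float:
    """Total analytic food volume currently in the scene, cm³."""
    return sum(analytic_mound_volume(m.a, m.h) for m in spec.mounds)


def simulate_meal(
    spec: SceneSpec,
    bite_schedule: Sequence[tuple[float, str, float]],
    K: CameraIntrinsics,
) -> tuple[list[DepthFrame], GroundTruth]:
    """Render a frame sequence for a bite schedule.

    ``bite_schedule`` holds (minute, mound_id, fraction) entries with
    strictly increasing minutes. One frame is rendered at meal start and
    one after each bite; ground truth records the exactly removed volume
    per interval. Referencing a fully-eaten mound raises ``KeyError``.
    """
    minutes = [b[0] for b in bite_schedule]
    if any(m1 <= m0 for m0, m1 in zip(minutes, minutes[1:])):
        raise ParameterError("bite schedule times must be strictly increasing")
    frames = [render_depth(spec, K, timestamp=0.0, seed=spec.seed)]
    totals = [scene_food_volume(spec)]
    removed_list: list[float] = []
    plate_list: list[int] = []
    timestamps = [0.0]
    current = spec
    for k, (minute, mound_id, fraction) in enumerate(bite_schedule, start=1):
        plate_list.append(current.mound(mound_id).plate)
        current, removed = take_bite(current, mound_id, fraction)
        ts = minute * 60.0
        frames.append(
            render_depth(current, K, timestamp=ts, seed=spec.seed + k)
        )
        removed_list.append(removed)
        totals.append(scene_food_volume(current))
        timestamps.append(ts)
    return frames, GroundTruth(removed_list, plate_list, totals, timestamps)
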