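"""End-to-end meal analysis: frames in, nutrition report out.

Per frame the table cloud is built from depth, plates are located
geometrically (table-plane removal + clustering) and re-identified
against the previous frame by signature matching; per plate and per
consecutive frame pair the consumed volume is measured by registered
point-cloud differencing, then converted to weights, nutrients, and
eating speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import __version__
from .association import fuse_scores, hungarian_match, signature_from_cloud
from .change_volume import VolumeResult, consumed_volume
from .config import PipelineConfig
from .geometry import DepthFrame, PointCloud, crop_to_disk, depth_to_cloud, voxel_downsample
from .nutrition import (
    MealInterval,
    MealLedger,
    NutritionEntry,
    UnknownCategoryError,
    eating_speed,
    nutrient_totals,
)
from .segmentation import detect_plates

logger = logging.getLogger(__name__)

_DETECT_VOXEL = 0.004  # m; downsampling for plate detection only


@dataclass
class TrackedPlate:
    plate_id: int
    center: np.ndarray
    radius: float


def _locate_plates(
    cloud: PointCloud, config: PipelineConfig
) -> list[tuple[np.ndarray, float]]:
    coarse = voxel_downsample(cloud, _DETECT_VOXEL)
    return detect_plates(coarse, config.segmentation)


def _associate(
    tracked: list[TrackedPlate],
    detections: list[tuple[np.ndarray, float]],
    clouds: list[PointCloud],
    prev_clouds: dict[int, PointCloud],
    config: PipelineConfig,
    next_id: int,
) -> tuple[dict[int, int], int]:
    """Match current detections to tracked plates by fused signatures.

    Returns a detection-index -> plate-id mapping. Unmatched detections
    open new plate ids.
    """
    if not tracked:
        return {i: i for i in range(len(detections))}, len(detections)
    prev_sigs = [
        signature_from_cloud(prev_clouds[t.plate_id], t.radius) for t in tracked
    ]
    curr_sigs = [
        signature_from_cloud(clouds[i], det[1]) for i, det in enumerate(detections)
    ]
    scores = fuse_scores(prev_sigs, curr_sigs, config.association.weights)
    matches = hungarian_match(scores, config.association.min_score)
    mapping: dict[int, int] = {}
    for prev_idx, curr_idx in matches:
        if curr_idx is not None:
            mapping[curr_idx] = tracked[prev_idx].plate_id
    for i in range(len(detections)):
        if i not in mapping:
            mapping[i] = next_id
            next_id += 1
    return mapping, next_id


def analyze_meal(
    frames: Sequence[DepthFrame],
    table: Mapping[str, NutritionEntry],
    categories: Union[str, Mapping[int, str]],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run the full pipeline over a frame sequence.

    ``categories`` assigns a food category per plate id (or one category
    for all plates). Returns a report dict with per-interval records,
    totals, eating speed and diagnostics; ``reliable`` is False if any
    interval had an unreliable registration.
    """
    if len(frames) < 2:
        raise ValueError("meal analysis needs at least 2 frames")
    config = config or PipelineConfig()

    clouds = [depth_to_cloud(f) for f in frames]
    detections = _locate_plates(clouds[0], config)
    if not detections:
        raise ValueError("no plates detected in the first frame")
    tracked = [
        TrackedPlate(i, center, radius) for i, (center, radius) in enumerate(detections)
    ]
    next_id = len(tracked)
    margin = config.crop_margin
    prev_crops: dict[int, PointCloud] = {
        t.plate_id: crop_to_disk(clouds[0], t.center, t.radius, margin)
        for t in tracked
    }

    ledger = MealLedger()
    interval_diags: list[dict] = []
    all_reliable = True
    for k in range(1, len(frames)):
        dets = _locate_plates(clouds[k], config)
        crop_list = [
            crop_to_disk(clouds[k], c, r, margin) for c, r in dets
        ]
        mapping, next_id = _associate(
            tracked, dets, crop_list, prev_crops, config, next_id
        )
        new_tracked: list[TrackedPlate] = []
        new_crops: dict[int, PointCloud] = {}
        for det_idx, plate_id in sorted(mapping.items()):
            center, radius = dets[det_idx]
            new_tracked.append(TrackedPlate(plate_id, center, radius))
            new_crops[plate_id] = crop_list[det_idx]
            if plate_id not in prev_crops:
                continue  # plate appeared mid-meal; no interval to difference
            result: VolumeResult = consumed_volume(
                prev_crops[plate_id], crop_list[det_idx], config.change
            )
            all_reliable = all_reliable and result.reliable
            category = (
                categories if isinstance(categories, str) else categories[plate_id]
            )
            if category not in table:
                raise UnknownCategoryError(category)
            entry = table[category]
            weight = result.volume_cm3 * entry.density * entry.packing
            ledger.add(
                MealInterval(
                    timestamp=frames[k].timestamp,
                    plate_id=plate_id,
                    category=category,
                    volume_cm3=result.volume_cm3,
                    weight_g=weight,
                )
            )
            interval_diags.append(
                {
                    "frame": k,
                    "plate_id": plate_id,
                    "volume_cm3": result.volume_cm3,
                    "n_changed": result.n_changed,
                    "fitness": result.registration.fitness
                    if result.registration
                    else None,
                    "clamped_fraction": result.clamped_fraction,
                    "reliable": result.reliable,
                }
            )
        tracked = new_tracked
        prev_crops = new_crops

    totals = nutrient_totals(ledger, table)
    # eating speed over per-timestamp aggregates (plates share timestamps)
    by_ts: dict[float, tuple[float, float]] = {}
    for iv in ledger.intervals:
        v, w = by_ts.get(iv.timestamp, (0.0, 0.0))
        by_ts[iv.timestamp] = (v + iv.volume_cm3, w + iv.weight_g)
    agg = MealLedger()
    for ts in sorted(by_ts):
        v, w = by_ts[ts]
        agg.add(MealInterval(ts, -1, "", v, w))
    speeds, mean_speed = eating_speed(agg) if agg.intervals else ([], 0.0)
    return {
        "version": __version__,
        "config_hash": config.hash(),
        "intervals": [vars(iv) for iv in ledger.intervals],
        "total_volume_cm3": ledger.total_volume_cm3,
        "total_weight_g": ledger.total_weight_g,
        "nutrient_totals": totals,
        "eating_speed_g_per_min": speeds,
        "mean_eating_speed_g_per_min": mean_speed,
        "reliable": all_reliable,
        "diagnostics": interval_diags,
    }
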