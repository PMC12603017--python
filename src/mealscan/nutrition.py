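"""Volume -> weight -> nutrient accounting for sequential eating.

Weight conversion is ``weight = volume × ρ × μ`` where ρ is the food
density (g/cm³) and μ a dimensionless packing factor in (0, 1] that
corrects the apparent (stacked) volume seen by the depth camera down to
effective mass. Signed percentage error against a reference weighing is
``100 · (reference − estimated) / reference``, reported to two decimals.

A small demo nutrition table and the bundled reference meal measurements
(three single-food meals — broccoli, chicken, rice — weighed per bite on
a kitchen scale alongside the camera estimates) ship as package data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NUTRIENT_FIELDS = ("kcal", "protein_g", "carb_g", "fat_g", "fiber_g")


class UnknownCategoryError(KeyError):
    """Raised when a food category is absent from the nutrition table."""


@dataclass(frozen=True)
class NutritionEntry:
    """Per-category density, packing factor, and per-100 g nutrients."""

    category: str
    density: float  # g/cm^3
    packing: float  # dimensionless, (0, 1]
    kcal: float = 0.0
    protein_g: float = 0.0
    carb_g: float = 0.0
    fat_g: float = 0.0
    fiber_g: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not (0 < self.packing <= 1):
            raise ValueError("packing factor must be in (0, 1]")
        for name in NUTRIENT_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_nutrition_table(path) -> dict[str, NutritionEntry]:
    """Read a nutrition CSV (category, density_g_cm3, packing_mu, per-100 g
    nutrient columns) into a category-keyed table."""
    df = pd.read_csv(path)
    table = {}
    for _, row in df.iterrows():
        table[row["category"]] = NutritionEntry(
            category=row["category"],
            density=float(row["density_g_cm3"]),
            packing=float(row["packing_mu"]),
            kcal=float(row["kcal_100g"]),
            protein_g=float(row["protein_100g"]),
            carb_g=float(row["carb_100g"]),
            fat_g=float(row["fat_100g"]),
            fiber_g=float(row["fiber_100g"]),
        )
    return table


def default_nutrition_table() -> dict[str, NutritionEntry]:
    """The bundled demo nutrition table."""
    ref = importlib.resources.files("mealscan.data") / "nutrition_demo.csv"
    with importlib.resources.as_file(ref) as path:
        return load_nutrition_table(path)


def weight_from_volume(volume_cm3: float, density: float, packing: float) -> float:
    """weight (g) = volume (cm^3) × ρ (g/cm^3) × μ; no internal rounding."""
    if volume_cm3 < 0:
        raise ValueError("volume must be >= 0")
    return volume_cm3 * density * packing


def percent_error(reference_g: float, estimated_g: float) -> float:
    """Signed error 100·(reference − estimated)/reference, to 2 decimals.

    Positive means underestimation, negative overestimation."""
    if reference_g <= 0:
        raise ValueError("reference weight must be positive")
    return round(100.0 * (reference_g - estimated_g) / reference_g, 2)


def apportion_by_mask(
    mask: np.ndarray,
    weight_g: float,
    table: Mapping[str, NutritionEntry],
    legend: Mapping[int, str],
) -> dict[str, float]:
    """Split a weight over food classes by their pixel share of a class
    mask.

    ``mask`` holds small integer labels; 0 is reserved for background /
    invalid pixels and ignored. ``legend`` maps labels to category names,
    which must all exist in ``table``. The returned weights sum exactly to
    ``weight_g``.
    """
    mask = np.asarray(mask)
    labels, counts = np.unique(mask[mask != 0], return_counts=True)
    if counts.sum() == 0:
        raise ValueError("mask has no valid (non-zero) pixels")
    unknown = [int(l) for l in labels if l not in legend]
    if unknown:
        raise UnknownCategoryError(f"mask labels without a legend entry: {unknown}")
    missing = [legend[l] for l in labels if legend[l] not in table]
    if missing:
        raise UnknownCategoryError(f"categories missing from table: {missing}")
    total = counts.sum()
    return {
        legend[int(l)]: weight_g * (c / total) for l, c in zip(labels, counts)
    }


@dataclass
class MealInterval:
    """One sampling interval of a meal for one plate."""

    timestamp: float  # seconds since meal start
    plate_id: int
    category: str
    volume_cm3: float
    weight_g: float
    reference_g: Optional[float] = None
    error_pct: Optional[float] = None


@dataclass
class MealLedger:
    """Ordered per-interval records plus meal-level totals."""

    intervals: list[MealInterval] = field(default_factory=list)

    def add(self, interval: MealInterval) -> None:
        same_plate = [iv for iv in self.intervals if iv.plate_id == interval.plate_id]
        if same_plate and interval.timestamp <= same_plate[-1].timestamp:
            raise ValueError("timestamps must be strictly increasing per plate")
        self.intervals.append(interval)

    @property
    def total_volume_cm3(self) -> float:
        return sum(iv.volume_cm3 for iv in self.intervals)

    @property
    def total_weight_g(self) -> float:
        return sum(iv.weight_g for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(iv) for iv in self.intervals])


def nutrient_totals(
    ledger: MealLedger, table: Mapping[str, NutritionEntry]
) -> dict[str, float]:
    """Total nutrients: Σ weight_g × (per-100 g value) / 100."""
    totals = {name: 0.0 for name in NUTRIENT_FIELDS}
    for iv in ledger.intervals:
        if iv.category not in table:
            raise UnknownCategoryError(iv.category)
        entry = table[iv.category]
        for name in NUTRIENT_FIELDS:
            totals[name] += iv.weight_g * getattr(entry, name) / 100.0
    return totals


@dataclass
class MealSummary:
    ledger: MealLedger
    total_weight_g: float
    total_reference_g: Optional[float] = None
    total_error_pct: Optional[float] = None


def accumulate_meal(
    interval_volumes: Sequence[tuple[float, float]],
    entry: NutritionEntry,
    references_g: Optional[Sequence[float]] = None,
    plate_id: int = 0,
) -> MealSummary:
    """Build a ledger from per-interval (timestamp s, volume cm³) pairs.

    Each interval's weight follows the ρ·μ conversion; when reference
    weighings are supplied, per-interval and total signed percent errors
    are computed against them.
    """
    if references_g is not None and len(references_g) != len(interval_volumes):
        raise ValueError("references must match interval count")
    ledger = MealLedger()
    for i, (ts, vol) in enumerate(interval_volumes):
        if vol < 0:
            raise ValueError("volumes must be >= 0")
        w = weight_from_volume(vol, entry.density, entry.packing)
        ref = references_g[i] if references_g is not None else None
        err = percent_error(ref, w) if ref is not None else None
        ledger.add(
            MealInterval(ts, plate_id, entry.category, vol, w, ref, err)
        )
    total_w = ledger.total_weight_g
    total_ref = float(sum(references_g)) if references_g is not None else None
    total_err = percent_error(total_ref, total_w) if total_ref else None
    return MealSummary(ledger, total_w, total_ref, total_err)


def eating_speed(ledger: MealLedger) -> tuple[list[float], float]:
    """Per-interval consumption speeds (g/min) and the meal mean.

    Interval speed divides consumed weight by elapsed minutes since the
    previous sample; the first interval uses its own timestamp as the
    elapsed time from meal start (t = 0). Mean speed is total weight over
    total duration.
    """
    if len(ledger.intervals) < 1:
        raise ValueError("eating speed needs at least one interval")
    times = [iv.timestamp for iv in ledger.intervals]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("timestamps must be strictly increasing")
    if times[0] <= 0:
        raise ValueError("first interval timestamp must be positive")
    speeds = []
    prev = 0.0
    for iv in ledger.intervals:
        minutes = (iv.timestamp - prev) / 60.0
        speeds.append(iv.weight_g / minutes)
        prev = iv.timestamp
    mean = ledger.total_weight_g / (times[-1] / 60.0)
    return speeds, mean


# ---------------------------------------------------------------------------
# Bundled reference meals (per-bite scale weighings vs. camera volumes)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceMeal:
    """One single-food reference meal: per-sequence scale weights and
    camera volumes, plus an independent first-vs-last-frame volume."""

    food: str
    reference_g: tuple[float, ...]
    volumes_cm3: tuple[float, ...]
    no_sequencing_volume_cm3: float
    effective_factor: float  # ρ·μ product used for this food


def load_reference_meals() -> dict[str, ReferenceMeal]:
    ref = importlib.resources.files("mealscan.data") / "reference_meals.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    meals = {}
    for food, group in df.groupby("food", sort=False):
        seq = group[group["sequence"] > 0].sort_values("sequence")
        ws = group[group["sequence"] == 0]
        meals[food] = ReferenceMeal(
            food=food,
            reference_g=tuple(seq["reference_g"].astype(float)),
            volumes_cm3=tuple(seq["volume_cm3"].astype(float)),
            no_sequencing_volume_cm3=float(ws["volume_cm3"].iloc[0]),
            effective_factor=float(group["effective_factor"].iloc[0]),
        )
    return meals
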