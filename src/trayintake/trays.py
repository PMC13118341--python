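"""Tray data model, tare-corrected intake, nutrient totals and waste summaries.

The unit of analysis is the meal tray: a set of individually weighed food
items served to one patient at lunch or dinner.  Intake is measured by
difference — each item is weighed before and after the meal, and the empty
container (tare) weight is subtracted from both sides.  Nutrient totals are
obtained by applying per-100 g composition densities to the consumed grams.

Plate waste is the leftover mass; it is summarised in absolute terms, as a
share of total waste per diet, and normalised per tray served within each
diet (the "waste intensity" of a diet).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CompositionLookupError, DataError, UndefinedFractionError

COURSES = ("first", "second", "dessert", "side")
MEAL_SLOTS = ("lunch", "dinner")
DIARY_LEVELS = (0.0, 0.5, 1.0)

#: Policies for items whose post-meal weight exceeds the pre-meal weight
#: (added liquid, scale drift).  ``clamp`` sets intake to zero and counts the
#: event; ``keep`` returns the negative value; ``error`` raises.
NEGATIVE_INTAKE_POLICIES = ("clamp", "keep", "error")


@dataclass(frozen=True)
class FoodItemRecord:
    """One served food item with its gross weights and container tare.

    Packaged items recorded at net weight carry ``tare_g = 0``.
    """

    tray_id: str
    item_name: str
    food_class: str
    course: str
    gross_pre_g: float
    gross_post_g: float
    tare_g: float = 0.0

    def __post_init__(self) -> None:
        if self.course not in COURSES:
            raise DataError(
                f"tray {self.tray_id!r} item {self.item_name!r}: "
                f"unknown course {self.course!r} (expected one of {COURSES})"
            )
        for name in ("gross_pre_g", "gross_post_g", "tare_g"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DataError(
                    f"tray {self.tray_id!r} item {self.item_name!r}: "
                    f"{name} must be finite and >= 0, got {v!r}"
                )
        if self.tare_g > self.gross_pre_g or self.tare_g > self.gross_post_g:
            raise DataError(
                f"tray {self.tray_id!r} item {self.item_name!r}: tare "
                f"{self.tare_g} g exceeds a gross weight "
                f"(pre {self.gross_pre_g} g, post {self.gross_post_g} g)"
            )

    @property
    def net_pre_g(self) -> float:
        return self.gross_pre_g - self.tare_g

    @property
    def net_post_g(self) -> float:
        return self.gross_post_g - self.tare_g


@dataclass
class Tray:
    """A served tray: one patient, one meal slot, one or more items."""

    tray_id: str
    items: list[FoodItemRecord]
    diet_code: str = "Physiological Common"
    meal_slot: str = "lunch"
    patient_id: Optional[str] = None
    diary_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.items:
            raise DataError(f"tray {self.tray_id!r}: empty item list")
        if self.meal_slot not in MEAL_SLOTS:
            raise DataError(
                f"tray {self.tray_id!r}: meal slot {self.meal_slot!r} not in "
                f"{MEAL_SLOTS} (breakfast trays are out of scope)"
            )
        if self.diary_score is not None and self.diary_score not in DIARY_LEVELS:
            raise DataError(
                f"tray {self.tray_id!r}: diary score {self.diary_score!r} "
                f"not in {DIARY_LEVELS}"
            )
        for it in self.items:
            if it.tray_id != self.tray_id:
                raise DataError(
                    f"tray {self.tray_id!r}: item {it.item_name!r} carries "
                    f"foreign tray id {it.tray_id!r}"
                )

    @property
    def served_g(self) -> float:
        """Net pre-meal weight of the whole tray, grams."""
        return float(sum(it.net_pre_g for it in self.items))

    @property
    def leftover_g(self) -> float:
        return float(sum(it.net_post_g for it in self.items))


@dataclass(frozen=True)
class CompositionEntry:
    """Energy and macronutrient densities of a food class, per 100 g."""

    food_class: str
    energy_kcal_per_100g: float
    protein_g_per_100g: float
    carb_g_per_100g: float
    fat_g_per_100g: float

    def __post_init__(self) -> None:
        for name in (
            "energy_kcal_per_100g",
            "protein_g_per_100g",
            "carb_g_per_100g",
            "fat_g_per_100g",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DataError(
                    f"composition {self.food_class!r}: {name} must be finite "
                    f"and >= 0, got {v!r}"
                )


CompositionTable = Mapping[str, CompositionEntry]


def composition_table(entries: Iterable[CompositionEntry]) -> dict[str, CompositionEntry]:
    """Index composition entries by food class, rejecting duplicates."""
    table: dict[str, CompositionEntry] = {}
    for e in entries:
        if e.food_class in table:
            raise DataError(f"duplicate composition entry for {e.food_class!r}")
        table[e.food_class] = e
    return table


@dataclass
class IntakeResult:
    """Per-item and tray-total intake and nutrient accounting for one tray."""

    tray_id: str
    per_item: pd.DataFrame
    served_g: float
    leftover_g: float
    intake_g: float
    energy_kcal: float
    protein_g: float
    carb_g: float
    fat_g: float
    n_clamped: int = 0


@dataclass
class WasteSummary:
    """Leftover-mass accounting across a set of trays."""

    n_trays: int
    total_served_g: float
    total_waste_g: float
    waste_fraction: float
    per_diet: pd.DataFrame
    zero_waste: bool = False

    def to_dict(self) -> dict:
        return {
            "n_trays": self.n_trays,
            "total_served_g": self.total_served_g,
            "total_waste_g": self.total_waste_g,
            "waste_fraction": self.waste_fraction,
            "per_diet": self.per_diet.to_dict(orient="records"),
        }


def item_intake(item: FoodItemRecord, policy: str = "clamp") -> float:
    """Tare-corrected intake of one item, grams.

    intake = (gross_pre − tare) − (gross_post − tare).  A negative raw value
    is handled by *policy* (see :data:`NEGATIVE_INTAKE_POLICIES`).
    """
    if policy not in NEGATIVE_INTAKE_POLICIES:
        raise ValueError(f"unknown negative-intake policy {policy!r}")
    raw = item.net_pre_g - item.net_post_g
    if raw < 0:
        if policy == "error":
            raise DataError(
                f"tray {item.tray_id!r} item {item.item_name!r}: negative "
                f"intake {raw:.2f} g (post-meal weight above pre-meal)"
            )
        if policy == "clamp":
            return 0.0
    return float(raw)


def tray_intake(
    tray: Tray,
    composition: CompositionTable,
    policy: str = "clamp",
) -> IntakeResult:
    """Intake and nutrient totals for one tray.

    Per-item nutrients are ``intake_g × density / 100``; tray totals are the
    sums of the item values.  Every item's food class must resolve in
    *composition*.
    """
    rows = []
    n_clamped = 0
    for it in tray.items:
        if it.food_class not in composition:
            raise CompositionLookupError(
                f"tray {tray.tray_id!r}: no composition entry for food class "
                f"{it.food_class!r} (item {it.item_name!r})"
            )
        raw = it.net_pre_g - it.net_post_g
        intake = item_intake(it, policy)
        if raw < 0 and policy == "clamp":
            n_clamped += 1
        comp = composition[it.food_class]
        rows.append(
            {
                "item_name": it.item_name,
                "food_class": it.food_class,
                "course": it.course,
                "served_g": it.net_pre_g,
                "leftover_g": it.net_pre_g - intake,
                "intake_g": intake,
                "energy_kcal": intake * comp.energy_kcal_per_100g / 100.0,
                "protein_g": intake * comp.protein_g_per_100g / 100.0,
                "carb_g": intake * comp.carb_g_per_100g / 100.0,
                "fat_g": intake * comp.fat_g_per_100g / 100.0,
            }
        )
    df = pd.DataFrame(rows)
    return IntakeResult(
        tray_id=tray.tray_id,
        per_item=df,
        served_g=float(df["served_g"].sum()),
        leftover_g=float(df["leftover_g"].sum()),
        intake_g=float(df["intake_g"].sum()),
        energy_kcal=float(df["energy_kcal"].sum()),
        protein_g=float(df["protein_g"].sum()),
        carb_g=float(df["carb_g"].sum()),
        fat_g=float(df["fat_g"].sum()),
        n_clamped=n_clamped,
    )


def summarize_waste(trays: Sequence[Tray], policy: str = "clamp") -> WasteSummary:
    """Aggregate leftover mass over *trays*, overall and per diet code.

    ``share_of_total_waste_pct`` apportions total waste across diets;
    ``waste_per_tray_pct`` is the fraction of a diet's served mass that was
    discarded (the diet's waste intensity).  With zero total waste, shares
    are reported as 0 and the summary is flagged.
    """
    if not trays:
        raise DataError("summarize_waste needs at least one tray")
    recs = []
    for tr in trays:
        served = tr.served_g
        waste = sum(it.net_pre_g - item_intake(it, policy) for it in tr.items)
        recs.append({"diet_code": tr.diet_code, "served_g": served, "waste_g": waste})
    df = pd.DataFrame(recs)
    total_served = float(df["served_g"].sum())
    total_waste = float(df["waste_g"].sum())
    if total_served <= 0:
        raise UndefinedFractionError("zero total served weight: waste fraction undefined")
    per = (
        df.groupby("diet_code", sort=True)
        .agg(n_trays=("waste_g", "size"), served_g=("served_g", "sum"), waste_g=("waste_g", "sum"))
        .reset_index()
    )
    zero_waste = total_waste <= 0
    per["share_of_total_waste_pct"] = (
        0.0 if zero_waste else 100.0 * per["waste_g"] / total_waste
    )
    per["waste_per_tray_pct"] = np.where(
        per["served_g"] > 0, 100.0 * per["waste_g"] / per["served_g"], 0.0
    )
    return WasteSummary(
        n_trays=len(trays),
        total_served_g=total_served,
        total_waste_g=total_waste,
        waste_fraction=total_waste / total_served,
        per_diet=per,
        zero_waste=zero_waste,
    )
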