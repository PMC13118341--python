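"""CSV readers and writers for tray tables, composition tables and masks.

One fixed tray-table schema is used throughout the package (one row per
item, tray-level fields repeated), so synthetic cohorts and hand-entered
datasets travel through the same loader with the same validation.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataError
from .trays import (
    CompositionEntry,
    FoodItemRecord,
    IntakeResult,
    Tray,
    composition_table,
)

PathLike = Union[str, "os.PathLike[str]"]

#: Fixed tray-table header. ``true_intake_g``, ``diary_score`` and
#: ``ai_estimate_g`` may be empty for real-world data.
TRAY_COLUMNS = [
    "tray_id",
    "patient_id",
    "diet_code",
    "meal_slot",
    "item_name",
    "food_class",
    "course",
    "gross_pre_g",
    "gross_post_g",
    "tare_g",
    "true_intake_g",
    "diary_score",
    "ai_estimate_g",
]

MASK_COLUMNS = [
    "tray_id",
    "item_name",
    "food_class",
    "view_id",
    "stage",
    "area_px",
    "confidence",
]

COMPOSITION_COLUMNS = [
    "food_class",
    "energy_kcal_per_100g",
    "protein_g_per_100g",
    "carb_g_per_100g",
    "fat_g_per_100g",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{what}: missing required columns {missing}")


def trays_to_frame(trays: Sequence[Tray]) -> pd.DataFrame:
    """Flatten trays to the fixed one-row-per-item table."""
    rows = []
    for tr in trays:
        for it in tr.items:
            rows.append(
                {
                    "tray_id": tr.tray_id,
                    "patient_id": tr.patient_id if tr.patient_id is not None else "",
                    "diet_code": tr.diet_code,
                    "meal_slot": tr.meal_slot,
                    "item_name": it.item_name,
                    "food_class": it.food_class,
                    "course": it.course,
                    "gross_pre_g": it.gross_pre_g,
                    "gross_post_g": it.gross_post_g,
                    "tare_g": it.tare_g,
                    "true_intake_g": it.net_pre_g - it.net_post_g,
                    "diary_score": tr.diary_score if tr.diary_score is not None else "",
                    "ai_estimate_g": "",
                }
            )
    return pd.DataFrame(rows, columns=TRAY_COLUMNS)


def frame_to_trays(df: pd.DataFrame) -> list[Tray]:
    """Build :class:`Tray` objects from a tray table, with row-level errors.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    _require_columns(df, TRAY_COLUMNS[:10], "tray table")
    seen: set[tuple[str, str]] = set()
    trays: dict[str, Tray] = {}
    items: dict[str, list[FoodItemRecord]] = {}
    meta: dict[str, dict] = {}
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        tid = str(row["tray_id"])
        key = (tid, str(row["item_name"]))
        if key in seen:
            raise DataError(f"row {pos}: duplicate tray_id+item_name {key}")
        seen.add(key)
        try:
            item = FoodItemRecord(
                tray_id=tid,
                item_name=str(row["item_name"]),
                food_class=str(row["food_class"]),
                course=str(row["course"]),
                gross_pre_g=float(row["gross_pre_g"]),
                gross_post_g=float(row["gross_post_g"]),
                tare_g=float(row["tare_g"]),
            )
        except (DataError, ValueError) as exc:
            raise DataError(f"row {pos}: {exc}") from exc
        items.setdefault(tid, []).append(item)
        if tid not in meta:
            diary = row.get("diary_score", "")
            diary_val: Optional[float]
            if diary is None or (isinstance(diary, str) and diary.strip() == "") or (
                isinstance(diary, float) and np.isnan(diary)
            ):
                diary_val = None
            else:
                diary_val = float(diary)
            pid = row.get("patient_id", "")
            if pid is None or (isinstance(pid, float) and np.isnan(pid)) or str(pid) == "":
                pid_val = None
            else:
                pid_val = str(pid)
            meta[tid] = {
                "diet_code": str(row["diet_code"]),
                "meal_slot": str(row["meal_slot"]),
                "patient_id": pid_val,
                "diary_score": diary_val,
            }
    for tid, its in items.items():
        m = meta[tid]
        trays[tid] = Tray(tray_id=tid, items=its, **m)
    return list(trays.values())


def write_tray_csv(trays: Sequence[Tray], path: PathLike) -> None:
    trays_to_frame(trays).to_csv(path, index=False)


def read_tray_csv(path: PathLike) -> list[Tray]:
    df = pd.read_csv(
        path,
        dtype={"tray_id": str, "patient_id": str, "item_name": str},
        float_precision="round_trip",
    )
    return frame_to_trays(df)


def write_composition_csv(entries: Sequence[CompositionEntry], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "food_class": e.food_class,
                "energy_kcal_per_100g": e.energy_kcal_per_100g,
                "protein_g_per_100g": e.protein_g_per_100g,
                "carb_g_per_100g": e.carb_g_per_100g,
                "fat_g_per_100g": e.fat_g_per_100g,
            }
            for e in entries
        ],
        columns=COMPOSITION_COLUMNS,
    ).to_csv(path, index=False)


def read_composition_csv(path: PathLike) -> dict[str, CompositionEntry]:
    df = pd.read_csv(path)
    _require_columns(df, COMPOSITION_COLUMNS, "composition table")
    return composition_table(
        CompositionEntry(
            food_class=str(r["food_class"]),
            energy_kcal_per_100g=float(r["energy_kcal_per_100g"]),
            protein_g_per_100g=float(r["protein_g_per_100g"]),
            carb_g_per_100g=float(r["carb_g_per_100g"]),
            fat_g_per_100g=float(r["fat_g_per_100g"]),
        )
        for _, r in df.iterrows()
    )


def write_intake_report(results: Sequence[IntakeResult], path: PathLike) -> None:
    """Write one row of tray totals per :class:`IntakeResult`."""
    pd.DataFrame(
        [
            {
                "tray_id": r.tray_id,
                "served_g": r.served_g,
                "leftover_g": r.leftover_g,
                "intake_g": r.intake_g,
                "energy_kcal": r.energy_kcal,
                "protein_g": r.protein_g,
                "carb_g": r.carb_g,
                "fat_g": r.fat_g,
                "n_clamped": r.n_clamped,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_mask_csv(mask_frame: pd.DataFrame, path: PathLike) -> None:
    _require_columns(mask_frame, MASK_COLUMNS, "mask table")
    mask_frame.loc[:, MASK_COLUMNS].to_csv(path, index=False)


def read_mask_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"tray_id": str, "item_name": str, "view_id": str},
        float_precision="round_trip",
    )
    _require_columns(df, MASK_COLUMNS, "mask table")
    return df
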