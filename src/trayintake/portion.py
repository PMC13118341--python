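"""Desk-scale area-to-weight portion estimation with multi-view fusion.

A food item segmented in a calibrated camera view yields a mask area; mass
is predicted from that area by a per-class linear regression fitted under
the Smooth L1 (Huber-like) loss, which tolerates occasional gross mask
failures better than least squares.  Views are combined by
confidence-weighted fusion: each view's prediction is weighted by the
product of its learned reliability (inverse validation residual variance)
and the observation's own confidence, renormalised over the views actually
available.

Geometric calibration converts pixel areas to cm² per view using reference
solids of known top-face area (cubes and cylinders), so the regression
coefficients are resolution-independent.

Consumed mass per tray is the sum over items of max(0, predicted pre-meal
mass − predicted post-meal mass); an item absent from the post-meal image
is treated as fully consumed.

Datasets are split into train/validation/test at the meal level: all
observations of one tray (pre and post, all views) stay in one partition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import (
    CalibrationError,
    DataError,
    PairingError,
    PredictionError,
    SplitError,
)


@dataclass
class ViewGeometry:
    """A camera view and its calibrated spatial scale."""

    view_id: str
    elevation_deg: float = 90.0
    scale_cm2_per_px: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.elevation_deg <= 90.0:
            raise DataError(f"view {self.view_id!r}: elevation must be in (0, 90]")
        if self.scale_cm2_per_px is not None and self.scale_cm2_per_px <= 0:
            raise DataError(f"view {self.view_id!r}: calibrated scale must be > 0")


@dataclass(frozen=True)
class CalibrationSolid:
    """A reference solid observed in one view for geometric calibration."""

    shape: str  # "cube" or "cylinder"
    side_or_diameter_cm: float
    height_cm: float
    observed_area_px: float

    def __post_init__(self) -> None:
        if self.shape not in ("cube", "cylinder"):
            raise DataError(f"unknown calibration solid shape {self.shape!r}")
        if self.side_or_diameter_cm <= 0 or self.height_cm <= 0:
            raise DataError("calibration solid dimensions must be > 0")
        if self.observed_area_px <= 0:
            raise CalibrationError(
                f"{self.shape}: zero or negative observed area; cannot calibrate"
            )

    @property
    def top_face_area_cm2(self) -> float:
        if self.shape == "cube":
            return self.side_or_diameter_cm**2
        return math.pi * (self.side_or_diameter_cm / 2.0) ** 2


@dataclass(frozen=True)
class MaskObservation:
    """One segmented mask of one item in one view."""

    tray_id: str
    item_name: str
    food_class: str
    view_id: str
    area_px: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.area_px < 0:
            raise DataError(
                f"tray {self.tray_id!r} item {self.item_name!r}: negative mask area"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise DataError(
                f"tray {self.tray_id!r} item {self.item_name!r}: confidence "
                f"{self.confidence} outside [0, 1]"
            )


@dataclass
class CalibrationResult:
    """Per-view scale with per-solid residuals around the mean."""

    scale_cm2_per_px: float
    residuals: np.ndarray


def calibrate_view(solids: Sequence[CalibrationSolid]) -> CalibrationResult:
    """Estimate a view's cm²-per-pixel scale from reference solids.

    The scale is the mean over solids of true top-face area divided by
    observed pixel area; residuals are each solid's ratio minus the mean.
    """
    if not solids:
        raise CalibrationError("no calibration solids supplied")
    ratios = np.asarray(
        [s.top_face_area_cm2 / s.observed_area_px for s in solids], dtype=float
    )
    scale = float(ratios.mean())
    return CalibrationResult(scale_cm2_per_px=scale, residuals=ratios - scale)


def smooth_l1(residual: float, beta: float = 1.0):
    """Smooth L1 loss: 0.5 r²/beta for |r| < beta, |r| − 0.5 beta otherwise."""
    if beta <= 0:
        raise DataError(f"smooth L1 beta must be > 0, got {beta}")
    r = np.abs(np.asarray(residual, dtype=float))
    out = np.where(r < beta, 0.5 * r**2 / beta, r - 0.5 * beta)
    return float(out) if out.ndim == 0 else out


def _smooth_l1_grad(r: np.ndarray, beta: float) -> np.ndarray:
    return np.clip(r / beta, -1.0, 1.0)


def _fit_line_smooth_l1(x: np.ndarray, y: np.ndarray, beta: float) -> tuple[float, float]:
    """Fit y ≈ slope·x + intercept minimising mean Smooth L1 loss.

    Initialised at the least-squares solution and refined with L-BFGS using
    the analytic gradient; on noiseless data the initial point is already
    the minimiser.
    """
    A = np.vstack([x, np.ones_like(x)]).T
    theta0, *_ = np.linalg.lstsq(A, y, rcond=None)

    def objective(theta):
        r = theta[0] * x + theta[1] - y
        g = _smooth_l1_grad(r, beta)
        return float(np.mean(smooth_l1(r, beta))), np.array(
            [np.mean(g * x), np.mean(g)]
        )

    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
    )
    return float(res.x[0]), float(res.x[1])


@dataclass
class AreaWeightModel:
    """Per-(food class, view) linear area→mass coefficients plus fusion weights.

    ``coefficients`` maps (food_class, view_id) to (slope g/cm², intercept g);
    ``fusion_weights`` maps food_class to per-view weights summing to 1;
    ``scales`` maps view_id to its calibrated cm²/px factor.
    """

    coefficients: dict = field(default_factory=dict)
    fusion_weights: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    loss_beta: float = 1.0
    pooled_classes: list = field(default_factory=list)

    def views_for(self, food_class: str) -> list[str]:
        return sorted(v for (c, v) in self.coefficients if c == food_class)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "loss_beta": self.loss_beta,
            "scales": self.scales,
            "coefficients": [
                {"food_class": c, "view_id": v, "slope_g_per_cm2": s, "intercept_g": b}
                for (c, v), (s, b) in sorted(self.coefficients.items())
            ],
            "fusion_weights": {
                c: dict(sorted(w.items())) for c, w in sorted(self.fusion_weights.items())
            },
            "pooled_classes": sorted(self.pooled_classes),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "AreaWeightModel":
        return cls(
            coefficients={
                (r["food_class"], r["view_id"]): (r["slope_g_per_cm2"], r["intercept_g"])
                for r in d["coefficients"]
            },
            fusion_weights={c: dict(w) for c, w in d["fusion_weights"].items()},
            scales=dict(d["scales"]),
            loss_beta=float(d["loss_beta"]),
            pooled_classes=list(d.get("pooled_classes", [])),
        )

    @classmethod
    def load(cls, path) -> "AreaWeightModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SplitSpec:
    """Meal-level train/validation/test split specification."""

    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) != 3 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise SplitError(f"split fractions {f} must be positive and sum to 1")


def meal_level_split(trays: Sequence, spec: SplitSpec) -> tuple[list, list, list]:
    """Partition trays (or tray ids) into train/val/test without leakage.

    Every tray lands entirely in one partition; sizes follow
    largest-remainder rounding of the requested fractions; the shuffle is
    deterministic in ``spec.seed``.
    """
    items = list(trays)
    n = len(items)
    if n < 3:
        raise SplitError(f"need at least 3 trays to form 3 partitions, got {n}")
    ids = [getattr(t, "tray_id", t) for t in items]
    if len(set(ids)) != n:
        raise SplitError("duplicate tray ids in split input")
    raw = np.asarray(spec.fractions) * n
    sizes = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [items[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def _calibrated_area(model: AreaWeightModel, obs: MaskObservation) -> float:
    if obs.view_id not in model.scales:
        raise PredictionError(f"view {obs.view_id!r} has no calibration scale")
    return obs.area_px * model.scales[obs.view_id]


def _flat_pairs(pairs):
    """Yield (observation, weight) from pairs whose first slot may be a list."""
    for first, w in pairs:
        if isinstance(first, MaskObservation):
            yield first, w
        else:
            for o in first:
                yield o, w


def fit_area_weight(
    train: Sequence[tuple[MaskObservation, float]],
    scales: dict,
    val: Optional[Sequence[tuple[MaskObservation, float]]] = None,
    loss_beta: float = 1.0,
    min_pairs: int = 5,
) -> AreaWeightModel:
    """Fit per-class, per-view area→mass regressions under Smooth L1 loss.

    *scales* maps view_id to calibrated cm²/px.  Training (and validation)
    pairs may carry either one observation or a list of per-view
    observations of the same item in their first slot.  A (class, view)
    cell with fewer than *min_pairs* training pairs is skipped with a
    warning and the class falls back to a pooled fit across all of its
    views.  Fusion weights per class are proportional to the inverse
    residual variance of each view on *val* (or, absent a validation set,
    on the training data), normalised to sum to 1.
    """
    model = AreaWeightModel(scales=dict(scales), loss_beta=loss_beta)
    by_cell: dict[tuple[str, str], list[tuple[float, float]]] = {}
    by_class: dict[str, list[tuple[float, float]]] = {}
    for obs, w in _flat_pairs(train):
        if w < 0:
            raise DataError(f"negative training weight for {obs.item_name!r}")
        a = obs.area_px * _scale_of(scales, obs.view_id)
        by_cell.setdefault((obs.food_class, obs.view_id), []).append((a, w))
        by_class.setdefault(obs.food_class, []).append((a, w))

    classes = sorted(by_class)
    views = sorted({v for (_, v) in by_cell})
    for cls_ in classes:
        cells = {v: by_cell.get((cls_, v), []) for v in views}
        thin = [v for v, pairs in cells.items() if 0 < len(pairs) < min_pairs]
        if thin:
            warnings.warn(
                f"class {cls_!r}: views {thin} have < {min_pairs} training "
                f"pairs; using a pooled-view fit for this class",
                stacklevel=2,
            )
            pooled = by_class[cls_]
            if len(pooled) < min_pairs:
                warnings.warn(f"class {cls_!r}: skipped entirely", stacklevel=2)
                continue
            x, y = map(np.asarray, zip(*pooled))
            coef = _fit_line_smooth_l1(x.astype(float), y.astype(float), loss_beta)
            for v in views:
                if cells[v]:
                    model.coefficients[(cls_, v)] = coef
            model.pooled_classes.append(cls_)
        else:
            for v, pairs in cells.items():
                if not pairs:
                    continue
                x, y = map(np.asarray, zip(*pairs))
                model.coefficients[(cls_, v)] = _fit_line_smooth_l1(
                    x.astype(float), y.astype(float), loss_beta
                )

    _set_fusion_weights(model, val if val is not None else train)
    return model


def _scale_of(scales: dict, view_id: str) -> float:
    if view_id not in scales:
        raise CalibrationError(f"view {view_id!r} has no calibration scale")
    return scales[view_id]


def _set_fusion_weights(
    model: AreaWeightModel, pairs: Sequence[tuple[MaskObservation, float]]
) -> None:
    resid: dict[tuple[str, str], list[float]] = {}
    for obs, w in _flat_pairs(pairs):
        key = (obs.food_class, obs.view_id)
        if key not in model.coefficients:
            continue
        slope, intercept = model.coefficients[key]
        pred = slope * _calibrated_area(model, obs) + intercept
        resid.setdefault(key, []).append(pred - w)
    for cls_ in sorted({c for (c, _) in model.coefficients}):
        views = model.views_for(cls_)
        var = {}
        for v in views:
            r = np.asarray(resid.get((cls_, v), []), dtype=float)
            var[v] = float((r**2).mean()) if r.size else np.inf
        finite = [x for x in var.values() if np.isfinite(x)]
        floor = 1e-12 * (1.0 + (max(finite) if finite else 0.0))
        inv = {v: (0.0 if not np.isfinite(x) else 1.0 / (x + floor)) for v, x in var.items()}
        total = sum(inv.values())
        if total <= 0:  # no residual information at all: equal weights
            model.fusion_weights[cls_] = {v: 1.0 / len(views) for v in views}
        else:
            model.fusion_weights[cls_] = {v: inv[v] / total for v in views}


def predict_weight(
    model: AreaWeightModel,
    observations: Sequence[MaskObservation],
    mode: str = "multi_view",
    view: Optional[str] = None,
) -> float:
    """Predict one item's mass (grams) from its mask observations.

    ``single_view`` uses the designated *view* (or the only one present);
    ``multi_view`` combines per-view predictions with weights proportional
    to fusion_weight × observation confidence, renormalised over available
    views.  The result is clamped at 0.
    """
    if not observations:
        raise PredictionError("no mask observations supplied")
    cls_ = observations[0].food_class
    if any(o.food_class != cls_ for o in observations):
        raise PairingError("mixed food classes in one item's observations")

    usable = [o for o in observations if (cls_, o.view_id) in model.coefficients]
    if not usable:
        raise PredictionError(
            f"no usable view for class {cls_!r}; model knows {model.views_for(cls_)}"
        )

    def one(o: MaskObservation) -> float:
        slope, intercept = model.coefficients[(cls_, o.view_id)]
        return slope * _calibrated_area(model, o) + intercept

    if mode == "single_view":
        if view is None:
            if len(usable) != 1:
                raise PredictionError("single_view mode with several views needs view=")
            chosen = usable[0]
        else:
            matches = [o for o in usable if o.view_id == view]
            if not matches:
                raise PredictionError(f"view {view!r} not available for this item")
            chosen = matches[0]
        return max(0.0, one(chosen))
    if mode != "multi_view":
        raise ValueError(f"unknown prediction mode {mode!r}")

    fw = model.fusion_weights.get(cls_, {})
    weights = np.asarray([fw.get(o.view_id, 0.0) * o.confidence for o in usable])
    preds = np.asarray([one(o) for o in usable])
    if weights.sum() <= 0:
        weights = np.asarray([o.confidence for o in usable], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(usable))
    weights = weights / weights.sum()
    return max(0.0, float(weights @ preds))


def intake_from_images(
    model: AreaWeightModel,
    pre_masks: Sequence[MaskObservation],
    post_masks: Sequence[MaskObservation],
    mode: str = "multi_view",
    view: Optional[str] = None,
) -> float:
    """Estimated consumed grams for one tray from pre/post mask observations.

    Per item: consumed = max(0, predicted_pre − predicted_post); an item
    with no post-meal observation counts as fully consumed.
    """
    pre_by_item: dict[str, list[MaskObservation]] = {}
    for o in pre_masks:
        pre_by_item.setdefault(o.item_name, []).append(o)
    post_by_item: dict[str, list[MaskObservation]] = {}
    for o in post_masks:
        post_by_item.setdefault(o.item_name, []).append(o)
    unknown = set(post_by_item) - set(pre_by_item)
    if unknown:
        raise PairingError(f"post-meal items absent pre-meal: {sorted(unknown)}")

    consumed = 0.0
    for item, pre_obs in pre_by_item.items():
        post_obs = post_by_item.get(item)
        if post_obs is not None:
            pre_cls = pre_obs[0].food_class
            if any(o.food_class != pre_cls for o in post_obs):
                raise PairingError(
                    f"item {item!r}: food class changed between pre and post images"
                )
        pred_pre = predict_weight(model, pre_obs, mode, view)
        pred_post = predict_weight(model, post_obs, mode, view) if post_obs else 0.0
        consumed += max(0.0, pred_pre - pred_post)
    return consumed


@dataclass
class MaskMetrics:
    accuracy: float
    f1: float
    degenerate: bool = False  # both masks empty: metrics set to 1 by convention


def mask_metrics(predicted_mask, true_mask) -> MaskMetrics:
    """Pixel accuracy and F1 of a predicted binary mask against the truth."""
    p = np.asarray(predicted_mask).astype(bool)
    t = np.asarray(true_mask).astype(bool)
    if p.shape != t.shape:
        raise DataError(f"mask shape mismatch: {p.shape} vs {t.shape}")
    acc = float((p == t).mean())
    tp = float(np.logical_and(p, t).sum())
    fp = float(np.logical_and(p, ~t).sum())
    fn = float(np.logical_and(~p, t).sum())
    if tp + fp + fn == 0:
        return MaskMetrics(accuracy=1.0, f1=1.0, degenerate=True)
    f1 = 2 * tp / (2 * tp + fp + fn)
    return MaskMetrics(accuracy=acc, f1=f1)


@dataclass
class EvalReport:
    """Item-level weight-prediction accuracy on a held-out set."""

    n: int
    mae_g: float
    mape_pct: float
    per_class: pd.DataFrame
    per_view: pd.DataFrame


def evaluate(
    model: AreaWeightModel,
    test: Sequence[tuple[Sequence[MaskObservation], float]],
    mode: str = "multi_view",
) -> EvalReport:
    """MAE/MAPE of item mass predictions, with class and view breakdowns.

    *test* pairs each item's mask observations (all views) with its true
    mass.  MAPE is computed over items with positive true mass.  The
    per-view table reports single-view MAE for each view over the items in
    which that view is available.
    """
    if not test:
        raise DataError("empty test set")
    rows = []
    view_rows = []
    for obs_list, true_w in test:
        pred = predict_weight(model, list(obs_list), mode)
        rows.append(
            {
                "food_class": obs_list[0].food_class,
                "true_g": true_w,
                "pred_g": pred,
                "abs_err_g": abs(pred - true_w),
            }
        )
        for o in obs_list:
            if (o.food_class, o.view_id) in model.coefficients:
                sv = predict_weight(model, [o], "single_view")
                view_rows.append({"view_id": o.view_id, "abs_err_g": abs(sv - true_w)})
    df = pd.DataFrame(rows)
    pos = df["true_g"] > 0
    mape = (
        100.0 * float((df.loc[pos, "abs_err_g"] / df.loc[pos, "true_g"]).mean())
        if pos.any()
        else float("nan")
    )
    per_class = (
        df.groupby("food_class")
        .agg(n=("abs_err_g", "size"), mae_g=("abs_err_g", "mean"))
        .reset_index()
    )
    per_view = (
        pd.DataFrame(view_rows)
        .groupby("view_id")
        .agg(n=("abs_err_g", "size"), mae_g=("abs_err_g", "mean"))
        .reset_index()
        if view_rows
        else pd.DataFrame(columns=["view_id", "n", "mae_g"])
    )
    return EvalReport(
        n=len(df),
        mae_g=float(df["abs_err_g"].mean()),
        mape_pct=mape,
        per_class=per_class,
        per_view=per_view,
    )


def masks_to_observations(frame: pd.DataFrame) -> list[MaskObservation]:
    """Convert a mask table (see :mod:`trayintake.io`) to observations."""
    return [
        MaskObservation(
            tray_id=str(r.tray_id),
            item_name=str(r.item_name),
            food_class=str(r.food_class),
            view_id=str(r.view_id),
            area_px=float(r.area_px),
            confidence=float(r.confidence),
        )
        for r in frame.itertuples()
    ]
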