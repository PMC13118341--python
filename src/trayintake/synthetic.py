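"""Synthetic tray-cohort generator with the study's measurement-error structure.

No tray-level dataset is publicly deposited, so every downstream analysis
in this package is exercised on synthetic cohorts whose statistical
structure mirrors the hospital study design:

* a cohort of patients, each contributing several lunch/dinner trays of a
  fixed diet code, with per-course served weights drawn around standard
  portion sizes;
* a consumption model with point masses at zero and full intake and a
  Beta-distributed partial component, so all three diary categories occur;
* a nursing misreporting channel: the true consumed fraction is first
  discretized on the diary scale, then the recorded score is drawn from a
  3×3 confusion matrix whose default is skewed toward upward adjacent
  errors (diaries over-report at the "all" level);
* an AI observation model with additive Gaussian error at the
  study-reported magnitudes (bias −41.1 g, SD 30.9 g), clamped at zero;
* per-class, per-view mask-area statistics (area per gram with lognormal
  dispersion) standing in for instance-segmentation output.

Ground truth (the consumed grams of every item) is retained alongside all
observations, and patient identifiers are generated so that naive and
patient-aware resampling can be compared on synthetic data.

All randomness flows from one master seed; each generator concern (cohort
structure, served weights, consumption, nursing, AI, masks) owns its own
stream derived from the seed by a fixed offset, so adding draws to one
concern never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .categorical import categorize_array
from .continuous import PairedIntake
from .errors import ConfigurationError, MaskModelLookupError
from .io import MASK_COLUMNS, TRAY_COLUMNS
from .portion import MaskObservation
from .trays import CompositionEntry, FoodItemRecord, Tray, composition_table

#: Fixed per-concern stream offsets under the master seed.
_STREAMS = {"structure": 0, "serving": 1, "consumption": 2, "nursing": 3, "ai": 4, "mask": 5}

DEFAULT_VIEWS = ("top", "lat1", "lat2", "lat3")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class ItemTemplate:
    """Served-weight distribution and container tare for one food class."""

    item_name: str
    food_class: str
    course: str
    mean_g: float
    sd_g: float
    tare_g: float = 0.0


#: Standard five-item hospital tray (net served weights; total mean 650 g,
#: in line with ~235 kg served over 362 trays).
DEFAULT_ITEM_TEMPLATES = (
    ItemTemplate("Pasta with tomato", "first_course", "first", 250.0, 30.0, 250.0),
    ItemTemplate("Main course", "main_course", "second", 180.0, 25.0, 350.0),
    ItemTemplate("Vegetables", "vegetables", "second", 90.0, 15.0, 350.0),
    ItemTemplate("Fruit puree", "dessert", "dessert", 100.0, 10.0, 150.0),
    ItemTemplate("Bread", "bread", "side", 30.0, 5.0, 0.0),  # packaged, net weight
)

#: Diet codes with sampling weights (study frequencies where reported).
DEFAULT_DIET_CATALOG = (
    ("Physiological Common", 0.340),
    ("Controlled Carbohydrates 1850 kcal", 0.213),
    ("Controlled Carbohydrates 1500 kcal", 0.144),
    ("Physiological Soft", 0.130),
    ("Low Sodium + Controlled Carbohydrates", 0.100),
    ("Re-Feeding Phase 2", 0.073),
)


def default_composition() -> dict[str, CompositionEntry]:
    """Plausible per-100 g densities for the default synthetic food classes."""
    rows = [
        ("first_course", 160.0, 5.0, 30.0, 2.5),
        ("main_course", 180.0, 15.0, 5.0, 11.0),
        ("vegetables", 35.0, 1.5, 5.0, 0.5),
        ("dessert", 55.0, 0.8, 12.0, 0.3),
        ("bread", 270.0, 9.0, 52.0, 2.0),
    ]
    return composition_table(
        CompositionEntry(c, e, p, cb, f) for c, e, p, cb, f in rows
    )


@dataclass
class ConsumptionModel:
    """Mixture over consumed fraction: zero / full / Beta partial component."""

    p_zero: float = 0.05
    p_full: float = 0.40
    p_partial: float = 0.55
    beta_a: float = 2.0
    beta_b: float = 2.0

    def validate(self) -> None:
        w = (self.p_zero, self.p_full, self.p_partial)
        if any(x < 0 for x in w):
            raise ConfigurationError("consumption_model: mixture weights must be >= 0")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"consumption_model: mixture weights {w} must sum to 1"
            )
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ConfigurationError("consumption_model: Beta parameters must be > 0")


#: Default diary confusion matrix (rows: true category none/half/all; columns:
#: recorded category).  Errors are adjacent-only and skewed upward from
#: "half" to "all"; the magnitudes are calibrated so the nursing-derived
#: gram error over trays with non-zero intake averages ≈ +12 g.
DEFAULT_NURSING_CONFUSION = np.array(
    [
        [0.85, 0.15, 0.00],
        [0.05, 0.73, 0.22],
        [0.00, 0.19, 0.81],
    ]
)


@dataclass
class NursingModel:
    """Per-true-category diary confusion probabilities (3×3, rows sum to 1)."""

    confusion: np.ndarray = field(
        default_factory=lambda: DEFAULT_NURSING_CONFUSION.copy()
    )

    def validate(self) -> None:
        c = np.asarray(self.confusion, dtype=float)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ConfigurationError(
                "nursing_model.confusion must be a non-negative 3×3 matrix"
            )
        bad = np.flatnonzero(np.abs(c.sum(axis=1) - 1.0) > 1e-12)
        if bad.size:
            raise ConfigurationError(
                f"nursing_model.confusion rows {bad.tolist()} do not sum to 1"
            )


@dataclass
class AIErrorModel:
    """Additive Gaussian gram error of the AI stream, clamped at zero."""

    bias_g: float = -41.1
    sd_g: float = 30.9

    def validate(self) -> None:
        if self.sd_g < 0:
            raise ConfigurationError(f"ai_error_model.sd_g must be >= 0, got {self.sd_g}")


def default_mask_model() -> "MaskModel":
    top = {"first_course": 12.0, "main_course": 10.0, "vegetables": 15.0,
           "dessert": 9.0, "bread": 20.0}
    area_per_g = {}
    cv = {}
    # CVs Monte-Carlo-calibrated so the fitted pipeline's tray-level MAE
    # lands near one tenth of the mean tray weight (the reported real-world
    # performance level); lateral views are noisier than the top-down view.
    for cls_, apg in top.items():
        area_per_g[(cls_, "top")] = apg
        cv[(cls_, "top")] = 0.25
        for v in ("lat1", "lat2", "lat3"):
            area_per_g[(cls_, v)] = 0.6 * apg  # foreshortened lateral views
            cv[(cls_, v)] = 0.42
    return MaskModel(area_per_g=area_per_g, cv=cv)


@dataclass
class MaskModel:
    """Per-(food class, view) mask-area statistics: mean px/g and CV."""

    area_per_g: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)

    def validate(self) -> None:
        for key, v in self.area_per_g.items():
            if v <= 0:
                raise ConfigurationError(
                    f"mask_model.area_per_g[{key}] must be > 0, got {v}"
                )
        for key, v in self.cv.items():
            if v < 0:
                raise ConfigurationError(f"mask_model.cv[{key}] must be >= 0, got {v}")

    def lookup(self, food_class: str, view_id: str) -> tuple[float, float]:
        key = (food_class, view_id)
        if key not in self.area_per_g:
            raise MaskModelLookupError(
                f"no mask-area statistics for class {food_class!r}, view {view_id!r}"
            )
        return self.area_per_g[key], self.cv.get(key, 0.0)


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Defaults reproduce the study conditions: 67 patients contributing on
    average 5.4 lunch/dinner trays (≈362 trays), standard five-item trays
    averaging 650 g served, and observation channels at the study-reported
    error magnitudes.
    """

    n_patients: int = 67
    trays_per_patient_mean: float = 5.4
    diet_catalog: Sequence[tuple[str, float]] = DEFAULT_DIET_CATALOG
    item_templates: Sequence[ItemTemplate] = DEFAULT_ITEM_TEMPLATES
    consumption_model: ConsumptionModel = field(default_factory=ConsumptionModel)
    nursing_model: NursingModel = field(default_factory=NursingModel)
    ai_error_model: AIErrorModel = field(default_factory=AIErrorModel)
    mask_model: MaskModel = field(default_factory=default_mask_model)
    views: Sequence[str] = DEFAULT_VIEWS
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.trays_per_patient_mean <= 0:
            raise ConfigurationError("trays_per_patient_mean must be > 0")
        if not self.diet_catalog:
            raise ConfigurationError("diet_catalog must be non-empty")
        weights = np.asarray([w for _, w in self.diet_catalog], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ConfigurationError("diet_catalog weights must be >= 0 with a positive sum")
        if not self.item_templates:
            raise ConfigurationError("item_templates must be non-empty")
        for t in self.item_templates:
            if t.sd_g < 0:
                raise ConfigurationError(
                    f"item_templates[{t.item_name!r}].sd_g must be >= 0"
                )
            if t.mean_g <= 0:
                raise ConfigurationError(
                    f"item_templates[{t.item_name!r}].mean_g must be > 0"
                )
        self.consumption_model.validate()
        self.nursing_model.validate()
        self.ai_error_model.validate()
        self.mask_model.validate()


# ---------------------------------------------------------------------------
# Elementary observation channels

def _draw_diary_scores(
    true_fractions: np.ndarray, confusion: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised diary channel: categorize, then draw from the confusion row."""
    cats = categorize_array(true_fractions)
    cum = np.asarray(confusion, dtype=float).cumsum(axis=1)[cats]
    u = rng.uniform(size=len(cats))
    recorded = (u[:, None] > cum).sum(axis=1)
    return recorded * 0.5


def generate_diary_score(
    true_fraction: float, nursing_model: NursingModel, rng: np.random.Generator
) -> float:
    """Recorded diary score for one tray's true consumed fraction."""
    nursing_model.validate()
    return float(
        _draw_diary_scores(np.asarray([true_fraction]), nursing_model.confusion, rng)[0]
    )


def generate_ai_estimate(
    true_intake_g: float, ai_error_model: AIErrorModel, rng: np.random.Generator
) -> float:
    """AI gram estimate: max(0, true + bias + Gaussian noise)."""
    ai_error_model.validate()
    if true_intake_g < 0:
        raise ConfigurationError(f"true intake must be >= 0, got {true_intake_g}")
    noise = rng.normal(0.0, ai_error_model.sd_g) if ai_error_model.sd_g > 0 else 0.0
    return max(0.0, true_intake_g + ai_error_model.bias_g + noise)


def _lognormal_factors(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean lognormal multipliers with the requested coefficient of variation."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=size))


def generate_mask_observations(
    item_weight_g: float,
    food_class: str,
    mask_model: MaskModel,
    views: Sequence[str],
    rng: np.random.Generator,
    tray_id: str = "T00000",
    item_name: str = "item",
) -> list[MaskObservation]:
    """One mask observation per view for one item at a given true mass."""
    if item_weight_g < 0:
        raise ConfigurationError("item weight must be >= 0")
    out = []
    for v in views:
        apg, cv = mask_model.lookup(food_class, v)
        if item_weight_g == 0:
            area = 0.0
        else:
            area = item_weight_g * apg * float(_lognormal_factors(cv, None, rng))
        out.append(
            MaskObservation(
                tray_id=tray_id, item_name=item_name, food_class=food_class,
                view_id=v, area_px=area, confidence=1.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort generation

@dataclass
class SyntheticCohort:
    """A generated cohort with ground truth beside every observation."""

    trays: list[Tray]
    true_fraction: np.ndarray
    ai_estimates_g: np.ndarray
    ai_clamp_count: int
    config: GeneratorConfig
    mask_observations: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return len(self.trays)

    @property
    def served_g(self) -> np.ndarray:
        return np.asarray([t.served_g for t in self.trays])

    @property
    def true_intake_g(self) -> np.ndarray:
        """Tray-level consumed grams (identical to the weighed gold standard)."""
        return self.served_g - np.asarray([t.leftover_g for t in self.trays])

    @property
    def diary_scores(self) -> np.ndarray:
        return np.asarray([t.diary_score for t in self.trays], dtype=float)

    def nursing_pairs(self) -> list[PairedIntake]:
        """Diary-derived grams (score × served) paired with weighed intake."""
        served = self.served_g
        gold = self.true_intake_g
        return [
            PairedIntake(
                tray_id=t.tray_id, gold_g=g, estimate_g=t.diary_score * s,
                method="nursing", patient_id=t.patient_id,
            )
            for t, g, s in zip(self.trays, gold, served)
        ]

    def ai_pairs(self) -> list[PairedIntake]:
        gold = self.true_intake_g
        return [
            PairedIntake(
                tray_id=t.tray_id, gold_g=g, estimate_g=e,
                method="ai", patient_id=t.patient_id,
            )
            for t, g, e in zip(self.trays, gold, self.ai_estimates_g)
        ]

    def to_tray_frame(self) -> pd.DataFrame:
        """Fixed-header tray table (one row per item, tray fields repeated)."""
        rows = []
        for t, ai in zip(self.trays, self.ai_estimates_g):
            for it in t.items:
                rows.append(
                    (
                        t.tray_id, t.patient_id, t.diet_code, t.meal_slot,
                        it.item_name, it.food_class, it.course,
                        it.gross_pre_g, it.gross_post_g, it.tare_g,
                        it.net_pre_g - it.net_post_g, t.diary_score, ai,
                    )
                )
        return pd.DataFrame(rows, columns=TRAY_COLUMNS)

    def mask_items(
        self, tray_ids: Optional[Sequence[str]] = None, stages: Sequence[str] = ("pre", "post")
    ) -> list[tuple[list[MaskObservation], float]]:
        """Group mask rows into (observations-per-item, true mass) pairs.

        Pre-meal items carry the served net weight, post-meal items the
        leftover net weight — the mask→weight training/evaluation currency.
        """
        if self.mask_observations is None:
            raise ConfigurationError("cohort was generated without mask observations")
        df = self.mask_observations
        if tray_ids is not None:
            df = df[df["tray_id"].isin(set(tray_ids))]
        df = df[df["stage"].isin(stages)]
        out = []
        for (_, _, _, w), grp in df.groupby(
            ["tray_id", "item_name", "stage", "true_weight_g"], sort=True
        ):
            obs = [
                MaskObservation(
                    tray_id=r.tray_id, item_name=r.item_name, food_class=r.food_class,
                    view_id=r.view_id, area_px=r.area_px, confidence=r.confidence,
                )
                for r in grp.itertuples()
            ]
            out.append((obs, float(w)))
        return out

    def tray_masks(self, tray_id: str, stage: str) -> list[MaskObservation]:
        if self.mask_observations is None:
            raise ConfigurationError("cohort was generated without mask observations")
        df = self.mask_observations
        sel = df[(df["tray_id"] == tray_id) & (df["stage"] == stage)]
        return [
            MaskObservation(
                tray_id=r.tray_id, item_name=r.item_name, food_class=r.food_class,
                view_id=r.view_id, area_px=r.area_px, confidence=r.confidence,
            )
            for r in sel.itertuples()
        ]


def generate_cohort(
    config: GeneratorConfig, include_masks: bool = False
) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    Tray count is random around ``n_patients × trays_per_patient_mean``
    (Poisson per patient, at least one tray each).  Identical configs —
    including the seed — produce bit-identical cohorts.  Post-meal weights
    are exactly served − consumed, item-wise.
    """
    config.validate()
    rng_struct = _rng(config.seed, "structure")
    rng_serve = _rng(config.seed, "serving")
    rng_cons = _rng(config.seed, "consumption")
    rng_nurse = _rng(config.seed, "nursing")
    rng_ai = _rng(config.seed, "ai")
    rng_mask = _rng(config.seed, "mask")

    n_per_patient = np.maximum(
        1, rng_struct.poisson(config.trays_per_patient_mean, size=config.n_patients)
    )
    diets = [d for d, _ in config.diet_catalog]
    w = np.asarray([x for _, x in config.diet_catalog], dtype=float)
    patient_diet = rng_struct.choice(len(diets), size=config.n_patients, p=w / w.sum())

    n_trays = int(n_per_patient.sum())
    templates = list(config.item_templates)
    k = len(templates)
    served = np.empty((n_trays, k))
    for j, t in enumerate(templates):
        served[:, j] = np.clip(rng_serve.normal(t.mean_g, t.sd_g, size=n_trays), 1.0, None)

    cm = config.consumption_model
    u = rng_cons.uniform(size=n_trays)
    beta_draws = rng_cons.beta(cm.beta_a, cm.beta_b, size=n_trays)
    frac = np.where(u < cm.p_zero, 0.0, np.where(u < cm.p_zero + cm.p_full, 1.0, beta_draws))

    diary = _draw_diary_scores(frac, config.nursing_model.confusion, rng_nurse)

    tray_true = (served * frac[:, None]).sum(axis=1)
    raw_ai = tray_true + config.ai_error_model.bias_g + rng_ai.normal(
        0.0, config.ai_error_model.sd_g, size=n_trays
    )
    ai = np.maximum(0.0, raw_ai)
    ai_clamps = int((raw_ai < 0).sum())

    trays: list[Tray] = []
    idx = 0
    for p in range(config.n_patients):
        pid = f"P{p + 1:04d}"
        for m in range(int(n_per_patient[p])):
            tid = f"T{idx + 1:05d}"
            items = []
            for j, t in enumerate(templates):
                net_pre = float(served[idx, j])
                consumed = net_pre * float(frac[idx])
                items.append(
                    FoodItemRecord(
                        tray_id=tid, item_name=t.item_name, food_class=t.food_class,
                        course=t.course, gross_pre_g=net_pre + t.tare_g,
                        gross_post_g=net_pre - consumed + t.tare_g, tare_g=t.tare_g,
                    )
                )
            trays.append(
                Tray(
                    tray_id=tid, items=items, diet_code=diets[patient_diet[p]],
                    meal_slot="lunch" if m % 2 == 0 else "dinner",
                    patient_id=pid, diary_score=float(diary[idx]),
                )
            )
            idx += 1

    masks = None
    if include_masks:
        rows = []
        views = list(config.views)
        for i, tray in enumerate(trays):
            for it in tray.items:
                for stage, weight in (("pre", it.net_pre_g), ("post", it.net_post_g)):
                    for v in views:
                        apg, cv = config.mask_model.lookup(it.food_class, v)
                        if weight <= 0:
                            area = 0.0
                        else:
                            area = weight * apg * float(
                                _lognormal_factors(cv, None, rng_mask)
                            )
                        rows.append(
                            (
                                tray.tray_id, it.item_name, it.food_class, v,
                                stage, area, 1.0, weight,
                            )
                        )
        masks = pd.DataFrame(rows, columns=MASK_COLUMNS + ["true_weight_g"])

    return SyntheticCohort(
        trays=trays,
        true_fraction=frac,
        ai_estimates_g=ai,
        ai_clamp_count=ai_clamps,
        config=config,
        mask_observations=masks,
    )
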