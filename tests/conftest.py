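import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from trayintake import (
    CompositionEntry,
    FoodItemRecord,
    GeneratorConfig,
    Tray,
    composition_table,
    generate_cohort,
)

# Worked single-tray example: four items with printed pre/post gross weights
# (tare 0; the dessert and cheese are packaged, recorded at net weight).
WORKED_TRAY_ITEMS = [
    # (item, class, course, pre_g, post_g)
    ("Pasta with tomato", "pasta_tomato", "first", 256.0, 142.0),
    ("Stracchino", "stracchino", "second", 100.0, 0.0),
    ("Carrots", "carrots", "second", 79.0, 53.0),
    ("Fruit Puree", "fruit_puree", "dessert", 100.0, 0.0),
]

# Composition densities per 100 g reverse-engineered from the worked tray's
# per-item nutrient values (value / intake × 100).
WORKED_COMPOSITION = [
    #  class          kcal        protein      carb        fat
    ("pasta_tomato", 175.0, 4.49 / 1.14, 36.92 / 1.14, 36.92 / 1.14),
    ("stracchino", 314.0, 14.0, 2.6, 27.0),
    ("carrots", 64.0, 0.0, 0.0, 1.86 / 0.26),
    ("fruit_puree", 51.0, 0.9, 11.0, 0.5),
]


@pytest.fixture
def worked_tray() -> Tray:
    items = [
        FoodItemRecord(
            tray_id="TX001", item_name=n, food_class=c, course=crs,
            gross_pre_g=pre, gross_post_g=post, tare_g=0.0,
        )
        for n, c, crs, pre, post in WORKED_TRAY_ITEMS
    ]
    return Tray(tray_id="TX001", items=items, diary_score=0.5)


@pytest.fixture
def worked_composition():
    return composition_table(
        CompositionEntry(c, e, p, cb, f) for c, e, p, cb, f in WORKED_COMPOSITION
    )


@pytest.fixture(scope="session")
def small_cohort():
    """~120-tray default-parameter cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=22, seed=123))


@pytest.fixture(scope="session")
def mask_cohort():
    """~90-tray cohort with mask observations for portion-estimation tests."""
    return generate_cohort(
        GeneratorConfig(n_patients=18, trays_per_patient_mean=5.0, seed=7),
        include_masks=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
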