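"""Tare-corrected intake and nutrient accounting for a single tray.

Builds the worked four-item tray (pasta, fresh cheese, carrots, fruit
purée) from its pre/post-meal weights, applies a per-100 g composition
table, and prints per-item intakes and tray totals.
"""

from trayintake import CompositionEntry, FoodItemRecord, Tray, composition_table, tray_intake

items = [
    # (name, class, course, pre g, post g)
    ("Pasta with tomato", "pasta_tomato", "first", 256.0, 142.0),
    ("Stracchino", "stracchino", "second", 100.0, 0.0),
    ("Carrots", "carrots", "second", 79.0, 53.0),
    ("Fruit Puree", "fruit_puree", "dessert", 100.0, 0.0),
]
tray = Tray(
    tray_id="T0001",
    items=[
        FoodItemRecord("T0001", n, c, crs, pre, post, tare_g=0.0)
        for n, c, crs, pre, post in items
    ],
)

# densities per 100 g of each food class
composition = composition_table(
    [
        CompositionEntry("pasta_tomato", 175.0, 3.94, 32.39, 32.39),
        CompositionEntry("stracchino", 314.0, 14.0, 2.6, 27.0),
        CompositionEntry("carrots", 64.0, 0.0, 0.0, 7.15),
        CompositionEntry("fruit_puree", 51.0, 0.9, 11.0, 0.5),
    ]
)

res = tray_intake(tray, composition)
print(res.per_item[["item_name", "served_g", "leftover_g", "intake_g", "energy_kcal"]])
print(
    f"\ntray totals: served {res.served_g:.0f} g, intake {res.intake_g:.0f} g, "
    f"leftover {res.leftover_g:.0f} g"
)
print(
    f"nutrients consumed: {res.energy_kcal:.2f} kcal, protein {res.protein_g:.2f} g, "
    f"carbohydrate {res.carb_g:.2f} g, fat {res.fat_g:.2f} g"
)
print(
    "\nThe patient ate 340 of 535 served grams (64%); intake is computed per "
    "item as (pre − tare) − (post − tare) and nutrients as intake × density/100."
)
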