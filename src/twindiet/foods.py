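"""Bundled food catalogue used by the synthetic cohort generator.

Each item carries a canonical food-key id, a database-style description,
a typical portion text (quantity-bearing, so it scores as *complete* under
the structural quality rules), per-portion nutrient values, a meal-slot
affinity, and a beverage flag.  The catalogue is deliberately small
(~50 items): just enough vocabulary for frequency tables and co-occurrence
networks to have non-trivial structure at toy scale.

Co-draw structure: tea is usually taken with semi-skimmed milk, and salads
co-draw tomato + lettuce + cucumber, so the generated networks have a few
strong edges the way real one-day diet diaries do.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FoodItem:
    key_id: str
    description: str
    portion_text: str
    energy_kcal: float
    protein_g: float
    carbohydrate_g: float
    fat_g: float
    fibre_g: float
    slot: str  # breakfast | lunch | dinner | snack | any
    beverage: bool = False


CATALOGUE: list[FoodItem] = [
    # beverages -----------------------------------------------------------
    FoodItem("tea_black", "Tea, black, infusion, average", "1 mug (260 ml)", 2, 0.2, 0.2, 0.0, 0.0, "any", True),
    FoodItem("coffee_instant", "Coffee, instant, made with water", "1 mug (260 ml)", 5, 0.5, 0.8, 0.0, 0.0, "any", True),
    FoodItem("milk_semi", "Milk, semi-skimmed, pasteurised, average", "30 ml in drink", 14, 1.0, 1.4, 0.5, 0.0, "any", True),
    FoodItem("milk_whole", "Milk, whole, pasteurised, average", "200 ml glass", 132, 6.8, 9.4, 7.2, 0.0, "any", True),
    FoodItem("wine_red", "Wine, red", "1 glass (175 ml)", 119, 0.2, 0.5, 0.0, 0.0, "dinner", True),
    FoodItem("wine_white", "Wine, white, dry", "1 glass (175 ml)", 116, 0.2, 1.0, 0.0, 0.0, "dinner", True),
    FoodItem("orange_juice", "Orange juice, unsweetened", "1 glass (200 ml)", 72, 1.0, 16.4, 0.2, 0.2, "breakfast", True),
    FoodItem("water_tap", "Water, tap", "1 glass (250 ml)", 0, 0.0, 0.0, 0.0, 0.0, "any", True),
    # breakfast -----------------------------------------------------------
    FoodItem("porridge", "Porridge, made with semi-skimmed milk", "1 bowl (160 g)", 160, 7.7, 21.9, 4.3, 1.3, "breakfast"),
    FoodItem("muesli", "Muesli, Swiss style", "1 serving (50 g)", 181, 4.9, 36.1, 3.0, 3.2, "breakfast"),
    FoodItem("cornflakes", "Cornflakes, fortified", "1 bowl (30 g)", 113, 2.1, 25.3, 0.2, 0.9, "breakfast"),
    FoodItem("toast_white", "Bread, white, toasted", "1 slice (33 g)", 87, 3.1, 16.9, 0.5, 0.8, "breakfast"),
    FoodItem("toast_whole", "Bread, wholemeal, toasted", "1 slice (33 g)", 80, 3.5, 14.0, 0.9, 2.2, "breakfast"),
    FoodItem("butter", "Butter, salted", "thin spread (7 g)", 52, 0.0, 0.0, 5.7, 0.0, "breakfast"),
    FoodItem("marmalade", "Marmalade, orange", "1 tsp (15 g)", 39, 0.0, 10.4, 0.0, 0.1, "breakfast"),
    FoodItem("egg_boiled", "Egg, chicken, boiled", "1 medium (50 g)", 72, 7.0, 0.0, 4.9, 0.0, "breakfast"),
    FoodItem("egg_scrambled", "Egg, chicken, scrambled with milk", "2 eggs (120 g)", 296, 16.1, 0.7, 25.4, 0.0, "breakfast"),
    FoodItem("yoghurt_plain", "Yoghurt, whole milk, plain", "1 pot (125 g)", 99, 7.1, 9.8, 3.8, 0.0, "breakfast"),
    FoodItem("banana", "Banana, raw, flesh only", "1 medium (100 g)", 95, 1.2, 23.2, 0.3, 1.4, "any"),
    # lunch ---------------------------------------------------------------
    FoodItem("bread_roll", "Bread roll, white, soft", "1 roll (55 g)", 148, 5.1, 28.0, 1.6, 1.3, "lunch"),
    FoodItem("cheese_cheddar", "Cheese, cheddar, average", "1 portion (30 g)", 125, 7.6, 0.0, 10.4, 0.0, "lunch"),
    FoodItem("ham_slice", "Ham, premium, sliced", "2 slices (46 g)", 50, 9.4, 0.5, 1.2, 0.0, "lunch"),
    FoodItem("tuna_can", "Tuna, canned in brine, drained", "half can (60 g)", 59, 14.2, 0.0, 0.4, 0.0, "lunch"),
    FoodItem("soup_vegetable", "Soup, vegetable, canned", "1 bowl (220 g)", 81, 2.4, 14.7, 1.5, 2.4, "lunch"),
    FoodItem("tomato_raw", "Tomatoes, standard, raw", "1 medium (85 g)", 15, 0.6, 2.6, 0.3, 0.9, "lunch"),
    FoodItem("lettuce_raw", "Lettuce, average, raw", "1 handful (30 g)", 4, 0.2, 0.5, 0.1, 0.4, "lunch"),
    FoodItem("cucumber_raw", "Cucumber, raw, unpeeled", "5 slices (30 g)", 3, 0.2, 0.4, 0.0, 0.2, "lunch"),
    FoodItem("apple", "Apple, eating, raw, flesh and skin", "1 medium (112 g)", 53, 0.7, 13.0, 0.1, 1.4, "any"),
    FoodItem("crisps", "Potato crisps, ready salted", "1 bag (25 g)", 132, 1.4, 13.2, 8.2, 1.2, "lunch"),
    FoodItem("hummus", "Hummus, average", "1 tbsp (30 g)", 56, 2.2, 3.4, 3.8, 0.7, "lunch"),
    # dinner --------------------------------------------------------------
    FoodItem("chicken_roast", "Chicken, breast, roasted, meat only", "1 breast (120 g)", 178, 38.4, 0.0, 2.6, 0.0, "dinner"),
    FoodItem("salmon_grilled", "Salmon, grilled", "1 fillet (120 g)", 257, 29.0, 0.0, 15.6, 0.0, "dinner"),
    FoodItem("beef_mince", "Beef, mince, stewed", "1 serving (140 g)", 293, 30.3, 0.0, 19.0, 0.0, "dinner"),
    FoodItem("pasta_boiled", "Pasta, white, boiled", "1 serving (180 g)", 187, 6.5, 37.3, 1.3, 2.2, "dinner"),
    FoodItem("rice_boiled", "Rice, white, basmati, boiled", "1 serving (180 g)", 248, 5.2, 55.6, 0.7, 0.7, "dinner"),
    FoodItem("potato_boiled", "Potatoes, old, boiled", "2 medium (175 g)", 126, 3.2, 29.8, 0.2, 2.1, "dinner"),
    FoodItem("chips_oven", "Chips, oven, baked", "1 serving (165 g)", 268, 5.3, 49.7, 6.9, 3.8, "dinner"),
    FoodItem("broccoli", "Broccoli, boiled", "4 florets (85 g)", 20, 2.6, 1.1, 0.4, 2.2, "dinner"),
    FoodItem("carrots", "Carrots, old, boiled", "1 serving (60 g)", 14, 0.4, 2.9, 0.2, 1.5, "dinner"),
    FoodItem("peas", "Peas, frozen, boiled", "1 serving (70 g)", 48, 4.2, 6.5, 0.6, 3.6, "dinner"),
    FoodItem("tomato_sauce", "Pasta sauce, tomato based", "half jar (125 g)", 63, 1.5, 8.7, 2.4, 1.4, "dinner"),
    FoodItem("curry_veg", "Curry, vegetable, takeaway", "1 serving (350 g)", 368, 8.0, 31.5, 23.5, 7.0, "dinner"),
    # snacks --------------------------------------------------------------
    FoodItem("biscuit_digestive", "Biscuits, digestive, plain", "2 biscuits (30 g)", 141, 1.9, 18.6, 6.3, 0.9, "snack"),
    FoodItem("chocolate_milk", "Chocolate, milk, average", "4 squares (25 g)", 130, 1.9, 14.2, 7.4, 0.2, "snack"),
    FoodItem("cake_sponge", "Cake, sponge, with jam", "1 slice (60 g)", 181, 2.6, 34.4, 3.0, 0.5, "snack"),
    FoodItem("nuts_mixed", "Nuts, mixed, unsalted", "1 handful (25 g)", 151, 5.7, 2.0, 13.5, 1.5, "snack"),
    FoodItem("grapes", "Grapes, average", "1 handful (80 g)", 48, 0.3, 12.4, 0.1, 0.6, "snack"),
    FoodItem("cracker_wholemeal", "Crackers, wholemeal", "3 crackers (21 g)", 86, 2.1, 14.3, 2.4, 1.0, "snack"),
    FoodItem("scone_plain", "Scone, plain", "1 scone (48 g)", 174, 3.5, 25.8, 6.5, 0.9, "snack"),
]

BY_KEY: dict[str, FoodItem] = {item.key_id: item for item in CATALOGUE}

#: canonical ids dropped by the all-day co-occurrence network variant
BEVERAGE_EXCLUSIONS: frozenset[str] = frozenset(
    item.key_id
    for item in CATALOGUE
    if item.beverage and any(w in item.key_id for w in ("milk", "coffee", "tea", "wine"))
)

NUTRIENT_COLUMNS = ["energy_kcal", "protein_g", "carbohydrate_g", "fat_g", "fibre_g"]


def items_for_slot(slot: str) -> list[FoodItem]:
    """All catalogue items eligible for a meal slot ('any' items included)."""
    return [it for it in CATALOGUE if it.slot == slot or it.slot == "any"]
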