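"""Bundled default configuration tables.

Food-composition databases report nutrients by name (``"Glucose"``,
``"Protein"``); constraint-based models speak metabolite identifiers in a
VMH-style namespace (``glc_D``, ``trp_L``).  The tables below provide a
small, editable default bridge between the two worlds: which nutrient names
are macronutrients, which map to a metabolite identifier, the molecular
weight needed to convert mass to millimoles, and the macronutrient group
each metabolite belongs to.  Every loader accepts user overrides; nothing
here is hard-wired.
"""

from __future__ import annotations

#: Canonical macronutrient keys of a food record, all per 100 g of food.
MACRO_KEYS: tuple[str, ...] = (
    "energy_kcal",
    "lipid_g",
    "protein_g",
    "carbohydrate_g",
    "sugars_g",
    "fibre_g",
    "starch_g",
    "alcohol_g",
)

#: Macro keys that may enter the food-matching distance (total carbohydrate
#: is deliberately excluded; its sub-components sugars/fibre/starch are used).
DISTANCE_KEYS: tuple[str, ...] = (
    "energy_kcal",
    "lipid_g",
    "protein_g",
    "sugars_g",
    "fibre_g",
    "starch_g",
)

#: kcal released per gram of each macronutrient group (Atwater convention,
#: with the common 2 kcal/g value for fermentable fibre and 7 for ethanol).
ATWATER_KCAL_PER_G: dict[str, float] = {
    "carbohydrate": 4.0,
    "protein": 4.0,
    "lipid": 9.0,
    "fibre": 2.0,
    "alcohol": 7.0,
}

#: kJ per kcal (thermochemical calorie convention used on food labels).
KJ_PER_KCAL: float = 4.184

#: Recognized nutrient-name spellings for each macronutrient key.  Matching
#: is case-insensitive on the stripped nutrient name.
DEFAULT_MACRO_NAMES: dict[str, str] = {
    "energy": "energy_kcal",
    "total lipid (fat)": "lipid_g",
    "lipid": "lipid_g",
    "fat": "lipid_g",
    "protein": "protein_g",
    "carbohydrate, by difference": "carbohydrate_g",
    "carbohydrate": "carbohydrate_g",
    "sugars, total including nlea": "sugars_g",
    "sugars, total": "sugars_g",
    "sugars": "sugars_g",
    "fiber, total dietary": "fibre_g",
    "fibre": "fibre_g",
    "fiber": "fibre_g",
    "starch": "starch_g",
    "alcohol, ethyl": "alcohol_g",
    "alcohol": "alcohol_g",
}

#: Default nutrient-name -> metabolite-id mapping (VMH-style identifiers).
DEFAULT_NUTRIENT_MAP: dict[str, str] = {
    "glucose": "glc_D",
    "fructose": "fru",
    "sucrose": "sucr",
    "lactose": "lcts",
    "leucine": "leu_L",
    "tryptophan": "trp_L",
    "lysine": "lys_L",
    "alanine": "ala_L",
    "linoleic acid": "lnlc",
    "stearic acid": "ocdca",
    "palmitic acid": "hdca",
    "thiamin": "thm",
    "riboflavin": "ribflv",
    "cholesterol": "chsterol",
}

#: Default molecular weights, g/mol.
DEFAULT_MW: dict[str, float] = {
    "glc_D": 180.156,
    "fru": 180.156,
    "sucr": 342.296,
    "lcts": 342.296,
    "leu_L": 131.173,
    "trp_L": 204.225,
    "lys_L": 146.188,
    "ala_L": 89.093,
    "lnlc": 280.446,
    "ocdca": 284.477,
    "hdca": 256.424,
    "thm": 265.355,
    "ribflv": 376.364,
    "chsterol": 386.654,
}

#: Default macronutrient group per metabolite.  Anything unlisted is "other".
DEFAULT_GROUP: dict[str, str] = {
    "glc_D": "carbohydrate",
    "fru": "carbohydrate",
    "sucr": "carbohydrate",
    "lcts": "carbohydrate",
    "leu_L": "protein",
    "trp_L": "protein",
    "lys_L": "protein",
    "ala_L": "protein",
    "lnlc": "lipid",
    "ocdca": "lipid",
    "hdca": "lipid",
    "chsterol": "lipid",
    "thm": "other",
    "ribflv": "other",
}

#: Macronutrient groups used for metabolite-derived macro summaries.
GROUPS: tuple[str, ...] = ("carbohydrate", "protein", "lipid", "other")
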