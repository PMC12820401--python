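"""Synthetic fixtures: toy food databases and a toy whole-body-style model.

Everything the package needs to run end-to-end is generated here, with no
download.  The toy food database mimics the *processed* output of the real
USDA/FRIDA pipelines — per-100 g macronutrients plus measured metabolites
already converted to mmol — at a few dozen foods instead of ~14,000.  It
embeds the worked-example foods used throughout the documentation (a dried
date, a red apple, a cream cheese) with fixed identifiers, plus two planted
foods with known properties: a protein isolate whose metabolite coverage of
protein is exactly 80%, and a tryptophan supplement contributing 2 mmol of
tryptophan per gram (the optimizer oracle's candidate food).

The toy model is a deterministic whole-body-style network: a diet
compartment ``[d]`` feeding a cytosolic compartment ``[c]``, a maintenance
objective consuming ATP, leucine and a vitamin (thiamin), free excretion of
every dietary species, and a serotonin-synthesis target whose maximum flux
has the closed form ``trp uptake / 2`` — the oracle for optimizer tests.
The ``missing_essential_metabolite`` defect removes thiamin from every food,
so diets built from the defective database cannot satisfy maintenance until
feasibility repair re-adds it.

All outputs are regenerable byte-identically from the fixture seed; random
draws use a single explicit NumPy generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from ._defaults import ATWATER_KCAL_PER_G, DEFAULT_GROUP, DEFAULT_MW
from .diet_builder import ConsumedRow, EquivalentsConsumed
from .food_database import FoodDatabase, FoodRecord, mass_to_mmol

__all__ = [
    "FixtureSpec",
    "BASE_METABOLITES",
    "ESSENTIAL_CANDIDATES",
    "make_toy_food_db",
    "make_toy_wbm",
    "table1_food_description",
    "table2_equivalents_consumed",
    "write_fixture_files",
]

#: The metabolite pool of the toy world (all present in the toy model).
BASE_METABOLITES: tuple[str, ...] = ("glc_D", "fru", "leu_L", "trp_L", "lnlc", "thm")

#: Default candidate list for feasibility repair: the vitamin-like essential
#: first, then the amino acid the maintenance objective consumes.
ESSENTIAL_CANDIDATES: tuple[tuple[str, float], ...] = (("thm", 0.05), ("leu_L", 0.5))

_WORDS = ("barley", "oat", "rye", "lentil", "spinach", "carrot", "salmon",
          "yogurt", "walnut", "honey", "millet", "kale", "beet", "plum",
          "cherry", "bean", "pea", "corn", "rice", "quinoa")
_FORMS = ("raw", "cooked", "dried", "canned", "smoked", "fresh")


@dataclass
class FixtureSpec:
    """Parameters of one reproducible fixture set.

    ``n_apple_hits`` is the *total* number of database descriptions
    containing the word "apple" (the embedded red-apple record counts as
    one); the generated word bank otherwise never produces it, so keyword
    searches for "apple" have an exactly known hit count.
    """

    seed: int = 1
    n_foods: int = 30
    n_metabolites: int = 6
    defect: str | None = None  # None | "missing_essential_metabolite"
    n_apple_hits: int = 1

    def __post_init__(self) -> None:
        if self.n_foods < 1 or self.n_metabolites < 1:
            raise ValueError("n_foods and n_metabolites must be >= 1")
        if self.defect not in (None, "missing_essential_metabolite"):
            raise ValueError(f"unknown defect {self.defect!r}")
        if self.n_apple_hits < 1:
            raise ValueError("n_apple_hits counts the embedded red apple; must be >= 1")


def _metabolite_pool(spec: FixtureSpec) -> tuple[dict[str, float], dict[str, str]]:
    mws = {m: DEFAULT_MW[m] for m in BASE_METABOLITES}
    groups = {m: DEFAULT_GROUP[m] for m in BASE_METABOLITES}
    rng = np.random.default_rng(spec.seed + 7919)
    cycle = ("carbohydrate", "protein", "lipid", "other")
    for i in range(max(0, spec.n_metabolites - len(BASE_METABOLITES))):
        mid = f"synmet{i + 1:02d}"
        mws[mid] = float(np.round(rng.uniform(80.0, 600.0), 3))
        groups[mid] = cycle[i % 4]
    return mws, groups


def _embedded_records(defect: str | None) -> list[FoodRecord]:
    date = FoodRecord(
        food_id="168191", database_origin="usda", description="Dates, medjool, dried",
        macronutrients={"energy_kcal": 282.0, "lipid_g": 0.4, "protein_g": 2.5,
                        "carbohydrate_g": 75.0, "sugars_g": 63.0, "fibre_g": 8.0},
        metabolites={"glc_D": mass_to_mmol(30.0, DEFAULT_MW["glc_D"]),
                     "fru": mass_to_mmol(28.0, DEFAULT_MW["fru"]),
                     "leu_L": 1.0,
                     "thm": 0.2},
    )
    # macros are the worked-example red apple (150 g reference) rescaled to
    # per-100 g, so the documented item matches this record at distance 0
    apple = FoodRecord(
        food_id="1105430", database_origin="usda",
        description="Apples, red, raw, with skin",
        macronutrients={"energy_kcal": 91.4 / 1.5, "lipid_g": 0.1 / 1.5,
                        "protein_g": 0.4 / 1.5, "sugars_g": 15.5 / 1.5,
                        "carbohydrate_g": 14.0, "fibre_g": 1.6},
        metabolites={"glc_D": 13.0, "fru": 32.0},
    )
    cheese = FoodRecord(
        food_id="1215", database_origin="frida", description="Cheese, cream, full fat",
        macronutrients={"energy_kcal": 350.0, "lipid_g": 34.0, "protein_g": 6.0,
                        "carbohydrate_g": 4.0, "sugars_g": 3.5},
        metabolites={"leu_L": 4.0, "trp_L": 1.0, "lnlc": 8.0, "glc_D": 2.0},
    )
    # planted: leucine mass 8 g against 10 g reported protein -> 80% coverage
    isolate = FoodRecord(
        food_id="900001", database_origin="usda",
        description="Protein isolate, test formulation",
        macronutrients={"energy_kcal": 40.0, "protein_g": 10.0},
        metabolites={"leu_L": mass_to_mmol(8.0, DEFAULT_MW["leu_L"])},
    )
    # planted: 2 mmol tryptophan per gram, with a small unavoidable lipid load
    supplement = FoodRecord(
        food_id="900002", database_origin="usda",
        description="Supplement, tryptophan powder",
        macronutrients={"energy_kcal": 180.0,
                        "protein_g": 200.0 * DEFAULT_MW["trp_L"] / 1000.0,
                        "lipid_g": 2.0},
        metabolites={"trp_L": 200.0,
                     "lnlc": mass_to_mmol(2.0, DEFAULT_MW["lnlc"])},
    )
    records = [date, apple, cheese, isolate, supplement]
    if defect == "missing_essential_metabolite":
        for rec in records:
            rec.metabolites.pop("thm", None)
    return records


def make_toy_food_db(spec: FixtureSpec) -> FoodDatabase:
    """Generate the toy food database for a fixture spec.

    Foods beyond the embedded ones draw 2–4 metabolites from the pool with
    group-typical amounts; their reported macros are the metabolite-derived
    group masses divided by a factor in (0.7, 1.0], so metabolite coverage
    below 100% is exercised throughout.  Descriptions come from a word bank
    that never contains "apple"; ``spec.n_apple_hits`` extra apple-named
    records are planted on top (counting the embedded red apple).
    """
    mws, groups = _metabolite_pool(spec)
    db = FoodDatabase(molecular_weights=mws, metabolite_group=groups)
    for rec in _embedded_records(spec.defect):
        db.add(rec)

    rng = np.random.default_rng(spec.seed)
    pool = [m for m in mws if m != "thm" or spec.defect is None]
    amount_range = {"carbohydrate": (10.0, 150.0), "protein": (1.0, 40.0),
                    "lipid": (1.0, 30.0), "other": (0.01, 1.0)}

    n_random = max(0, spec.n_foods - len(db))
    for i in range(n_random):
        w1, w2 = rng.choice(_WORDS, size=2, replace=False)
        form = rng.choice(_FORMS)
        origin = "usda" if rng.random() < 0.7 else "frida"
        n_mets = int(rng.integers(2, 5))
        chosen = rng.choice(pool, size=min(n_mets, len(pool)), replace=False)
        metabolites = {}
        for met in chosen:
            lo, hi = amount_range[groups[met]]
            metabolites[str(met)] = float(np.round(rng.uniform(lo, hi), 4))
        derived = {g: 0.0 for g in ("carbohydrate", "protein", "lipid")}
        for met, mmol in metabolites.items():
            g = groups[met]
            if g in derived:
                derived[g] += mmol * mws[met] / 1000.0
        macros: dict[str, float] = {}
        for g, mass in derived.items():
            if mass <= 0:
                continue
            reported = mass / float(rng.uniform(0.7, 1.0))
            macros[{"carbohydrate": "carbohydrate_g", "protein": "protein_g",
                    "lipid": "lipid_g"}[g]] = float(np.round(reported, 4))
        carb = macros.get("carbohydrate_g", 0.0)
        if carb > 0:
            sugars = carb * float(rng.uniform(0.4, 0.8))
            fibre = carb * float(rng.uniform(0.05, 0.2))
            macros["sugars_g"] = float(np.round(sugars, 4))
            macros["fibre_g"] = float(np.round(fibre, 4))
            macros["starch_g"] = float(np.round(max(0.0, carb - sugars - fibre), 4))
        macros["energy_kcal"] = float(np.round(
            sum(ATWATER_KCAL_PER_G[g] * derived[g] for g in derived), 4))
        db.add(FoodRecord(
            food_id=str(800000 + i), database_origin=origin,
            description=f"{str(w1).capitalize()}, {w2}, {form}",
            macronutrients=macros, metabolites=metabolites))

    for i in range(spec.n_apple_hits - 1):
        db.add(FoodRecord(
            food_id=str(700000 + i), database_origin="usda",
            description=f"Apple, cultivar {i + 1:02d}, raw",
            macronutrients={"energy_kcal": 52.0, "sugars_g": 10.4, "protein_g": 0.3,
                            "lipid_g": 0.2, "carbohydrate_g": 13.8, "fibre_g": 2.4},
            metabolites={"glc_D": 12.0 + i * 0.01, "fru": 30.0}))
    db.validate()
    return db


def table1_food_description() -> pd.DataFrame:
    """The worked-example food-description table (one red apple, per 150 g)."""
    return pd.DataFrame([{
        "OriginalFood": "Red apple", "KeyWords": "Apple; Red",
        "ReferenceWeight(g)": 150, "Energy (kcal)": 91.4, "Lipid (g)": 0.1,
        "Protein (g)": 0.4, "Sugars (g)": 15.5,
    }])


def table2_equivalents_consumed() -> EquivalentsConsumed:
    """The worked-example equivalents-consumed table (two diets, three foods)."""
    return EquivalentsConsumed(rows=[
        ConsumedRow("Dried date", "168191", "usda", {"diet1": 50.0, "diet2": 80.0}),
        ConsumedRow("Red apple", "1105430", "usda", {"diet1": 100.0, "diet2": 0.0}),
        ConsumedRow("Cream cheese", "1215", "frida", {"diet1": 25.0, "diet2": 35.0}),
    ])


_BIG = 1e6


def make_toy_wbm(spec: FixtureSpec | None = None) -> Model:
    """Deterministic toy whole-body-style model.

    Compartments: ``[d]`` diet, ``[c]`` cytosol.  Every base metabolite has
    a diet exchange (open to uptake by default; applying a diet closes the
    rest), a transport into ``[c]``, and a free excretion route from ``[d]``
    so surplus dietary input can always leave.  Energy substrates yield ATP
    (glucose/fructose 2 each, linoleate 9); the maintenance objective
    ``WB_maintenance`` consumes 10 ATP + 0.1 leucine + 0.01 thiamin per unit
    flux.  The serotonin target ``SRTN_SYN`` consumes 2 tryptophan per unit,
    so its FBA maximum is exactly half the available tryptophan uptake.
    """
    model = Model("toy_wbm")
    d = {m: Metabolite(f"{m}[d]", name=m, compartment="d") for m in BASE_METABOLITES}
    c = {m: Metabolite(f"{m}[c]", name=m, compartment="c") for m in BASE_METABOLITES}
    atp = Metabolite("atp[c]", name="atp", compartment="c")
    srtn = Metabolite("srtn[c]", name="serotonin", compartment="c")

    rxns = []

    def add(rid, stoich, lb, ub):
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(stoich)
        rxns.append(r)
        return r

    for m in BASE_METABOLITES:
        add(f"Diet_EX_{m}[d]", {d[m]: -1.0}, -_BIG, 0.0)
        add(f"Excr_EX_{m}[d]", {d[m]: -1.0}, 0.0, _BIG)
        add(f"T_{m}", {d[m]: -1.0, c[m]: 1.0}, 0.0, _BIG)

    add("GLYC", {c["glc_D"]: -1.0, atp: 2.0}, 0.0, _BIG)
    add("FRUU", {c["fru"]: -1.0, atp: 2.0}, 0.0, _BIG)
    add("BOX", {c["lnlc"]: -1.0, atp: 9.0}, 0.0, _BIG)
    add("SRTN_SYN", {c["trp_L"]: -2.0, srtn: 1.0}, 0.0, _BIG)
    add("DM_srtn", {srtn: -1.0}, 0.0, _BIG)
    add("WB_maintenance", {atp: -10.0, c["leu_L"]: -0.1, c["thm"]: -0.01}, 0.0, _BIG)

    model.add_reactions(rxns)
    model.objective = "WB_maintenance"
    return model


def write_fixture_files(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write db.tsv, foodDescription.csv, equivalentsConsumed.csv and toy_model.xml."""
    from cobra.io import write_sbml_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "db": out / "db.tsv",
        "food_description": out / "foodDescription.csv",
        "equivalents_consumed": out / "equivalentsConsumed.csv",
        "model": out / "toy_model.xml",
    }
    make_toy_food_db(spec).save(paths["db"])
    table1_food_description().to_csv(paths["food_description"], index=False)

    eq = table2_equivalents_consumed()
    rows = []
    for row in eq.rows:
        rec = {"FoodName": row.food_name, "databaseID": row.food_id,
               "databaseOrigin": row.database_origin}
        for diet, g in row.grams.items():
            rec[f"{diet} (g)"] = g
        rows.append(rec)
    pd.DataFrame(rows).to_csv(paths["equivalents_consumed"], index=False)

    write_sbml_model(make_toy_wbm(spec), str(paths["model"]))
    return paths
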