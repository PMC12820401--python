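"""Compile consumed food equivalents into metabolite-resolved *in silico* diets.

The equivalents-consumed table links each chosen database food equivalent to
the grams eaten per day under one or more named diets.  For every food the
per-100 g metabolite amounts are divided by 100 and multiplied by the
consumed weight, then summed over foods, giving a diet as a vector of
mmol/day/person per metabolite — the unit a constraint-based model takes as
dietary uptake bounds.  The same accumulation yields two macronutrient
summaries: one from the macros the database reports, one re-derived from the
measured metabolites themselves, so the user can see how much of the diet
the model will actually "see".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._defaults import ATWATER_KCAL_PER_G, GROUPS, MACRO_KEYS
from .food_database import FoodDatabase, metabolite_derived_macros

__all__ = [
    "ConsumedRow",
    "EquivalentsConsumed",
    "InSilicoDiet",
    "build_diet",
    "energy_fractions",
    "compare_to_original",
    "read_equivalents_consumed",
    "write_diet_outputs",
]


@dataclass
class ConsumedRow:
    """One food equivalent with its consumed grams per diet."""

    food_name: str
    food_id: str
    database_origin: str
    grams: dict[str, float]  # diet name -> g/day

    def __post_init__(self) -> None:
        for diet, g in self.grams.items():
            if g < 0:
                raise ValueError(
                    f"{self.food_name!r}: negative consumed weight {g} g in diet {diet!r}")


@dataclass
class EquivalentsConsumed:
    """The rows of one equivalents-consumed table."""

    rows: list[ConsumedRow] = field(default_factory=list)

    @property
    def diet_names(self) -> list[str]:
        names: list[str] = []
        for row in self.rows:
            for d in row.grams:
                if d not in names:
                    names.append(d)
        return names

    def resolve(self, db: FoodDatabase) -> None:
        """Fail fast if any row does not resolve in the database."""
        bad = [(r.database_origin, r.food_id, r.food_name)
               for r in self.rows if (r.database_origin, r.food_id) not in db.records]
        if bad:
            lines = ", ".join(f"({o}, {i}, {n!r})" for o, i, n in bad)
            raise KeyError(f"rows not found in food database: {lines}")

    def consumption(self, diet_name: str) -> dict[tuple[str, str], float]:
        """(origin, id) -> g/day for one diet, rows with 0 g included."""
        out: dict[tuple[str, str], float] = {}
        for row in self.rows:
            g = row.grams.get(diet_name, 0.0)
            out[(row.database_origin, row.food_id)] = out.get(
                (row.database_origin, row.food_id), 0.0) + g
        return out


@dataclass
class InSilicoDiet:
    """One diet resolved to metabolites.

    ``flux`` is mmol/day/person per metabolite.  ``macros_database``
    accumulates the database-reported macronutrients (g/day; energy in
    kcal/day), ``macros_metabolite`` re-derives group masses (g/day) from the
    measured metabolites only.
    """

    diet_name: str
    flux: dict[str, float] = field(default_factory=dict)
    macros_database: dict[str, float] = field(default_factory=dict)
    macros_metabolite: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "InSilicoDiet":
        return InSilicoDiet(self.diet_name, dict(self.flux),
                            dict(self.macros_database), dict(self.macros_metabolite))


def build_diet(consumed: EquivalentsConsumed, db: FoodDatabase, diet_name: str) -> InSilicoDiet:
    """Compile one named diet into an :class:`InSilicoDiet`.

    ``flux[m] = Σ_foods metabolites[m]/100 × grams`` — per-100 g amounts
    scaled by consumed weight and summed.  Rows consumed at 0 g contribute
    nothing.  The operation is linear in the gram column and additive over
    rows.
    """
    if diet_name not in consumed.diet_names:
        raise KeyError(f"diet {diet_name!r} not present; have {consumed.diet_names}")
    consumed.resolve(db)

    diet = InSilicoDiet(diet_name=diet_name,
                        macros_database={k: 0.0 for k in MACRO_KEYS},
                        macros_metabolite={g: 0.0 for g in GROUPS})
    for row in consumed.rows:
        grams = row.grams.get(diet_name, 0.0)
        if grams == 0.0:
            continue
        rec = db.get(row.database_origin, row.food_id)
        scale = grams / 100.0
        for met, mmol_per_100g in rec.metabolites.items():
            diet.flux[met] = diet.flux.get(met, 0.0) + mmol_per_100g * scale
        for key, val in rec.macronutrients.items():
            diet.macros_database[key] += val * scale
        for group, mass in metabolite_derived_macros(rec, db).items():
            diet.macros_metabolite[group] += mass * scale
    return diet


def _group_masses(diet: InSilicoDiet, source: str) -> dict[str, float]:
    if source == "database":
        m = diet.macros_database
        return {
            "carbohydrate": m.get("carbohydrate_g", 0.0),
            "protein": m.get("protein_g", 0.0),
            "lipid": m.get("lipid_g", 0.0),
            "fibre": m.get("fibre_g", 0.0),
            "alcohol": m.get("alcohol_g", 0.0),
        }
    if source == "metabolite":
        return {g: v for g, v in diet.macros_metabolite.items() if g != "other"}
    raise ValueError(f"source must be 'database' or 'metabolite', got {source!r}")


def energy_fractions(
    diet: InSilicoDiet,
    factors: Mapping[str, float] | None = None,
    source: str = "database",
) -> dict[str, float] | None:
    """Fractional contribution of each macronutrient group to dietary energy.

    Group energy is mass (g/day) times its energy density (kcal/g; Atwater
    4/4/9 with fibre 2 and alcohol 7 by default); fractions are normalized
    to the total.  Computed either from the database-reported macros
    (``source="database"``) or from the metabolite-derived masses
    (``source="metabolite"``).  Returns ``None`` when total energy is zero
    (fractions undefined).
    """
    f = dict(factors or ATWATER_KCAL_PER_G)
    masses = _group_masses(diet, source)
    energies = {g: m * f[g] for g, m in masses.items() if g in f}
    total = sum(energies.values())
    if total == 0.0:
        return None
    return {g: e / total for g, e in energies.items()}


def compare_to_original(
    diet: InSilicoDiet,
    original_macros: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tabulate database vs metabolite-derived macros, optionally vs the original diet.

    One row per macronutrient group (plus energy).  With ``original_macros``
    (same keys as ``macros_database``, g/day or kcal/day) two difference
    columns are appended; without it the table has the two derived columns
    only.
    """
    rows = []
    met_for_key = {"carbohydrate_g": "carbohydrate", "protein_g": "protein",
                   "lipid_g": "lipid"}
    for key in MACRO_KEYS:
        row = {"macro": key, "database": diet.macros_database.get(key, 0.0)}
        group = met_for_key.get(key)
        row["metabolite"] = diet.macros_metabolite.get(group) if group else None
        if original_macros is not None:
            orig = original_macros.get(key)
            row["original"] = orig
            row["database_minus_original"] = (
                row["database"] - orig if orig is not None else None)
            row["metabolite_minus_original"] = (
                row["metabolite"] - orig
                if orig is not None and row["metabolite"] is not None else None)
        rows.append(row)
    return pd.DataFrame(rows)


def read_equivalents_consumed(path: str | Path) -> EquivalentsConsumed:
    """Read an equivalents-consumed CSV.

    Header: ``FoodName, databaseID, databaseOrigin`` followed by one column
    per diet whose name may carry a ``(g)`` unit suffix, e.g. ``diet1 (g)``.
    A food not consumed in some diet has 0 in that column.
    """
    df = pd.read_csv(path, dtype={"databaseID": str})
    required = ["FoodName", "databaseID", "databaseOrigin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    diet_cols = [c for c in df.columns if c not in required]
    if not diet_cols:
        raise ValueError(f"{path}: no diet columns found")
    rows = []
    for _, r in df.iterrows():
        grams = {}
        for col in diet_cols:
            name = col.removesuffix("(g)").strip() if col.endswith("(g)") else col.strip()
            grams[name] = float(r[col]) if pd.notna(r[col]) else 0.0
        rows.append(ConsumedRow(food_name=str(r["FoodName"]).strip(),
                                food_id=str(r["databaseID"]).strip(),
                                database_origin=str(r["databaseOrigin"]).strip(),
                                grams=grams))
    return EquivalentsConsumed(rows=rows)


def write_diet_outputs(
    diet: InSilicoDiet,
    out_dir: str | Path,
    original_macros: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write the flux vector, macro summary and energy-fraction tables for one diet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "flux": out / f"{diet.diet_name}_flux.csv",
        "macros": out / f"{diet.diet_name}_macros.csv",
        "energy": out / f"{diet.diet_name}_energy_fractions.csv",
    }
    pd.DataFrame(sorted(diet.flux.items()),
                 columns=["metabolite_id", "mmol_per_day"]).to_csv(paths["flux"], index=False)
    compare_to_original(diet, original_macros).to_csv(paths["macros"], index=False)
    rows = []
    for source in ("database", "metabolite"):
        fr = energy_fractions(diet, source=source)
        if fr is None:
            rows.append({"source": source, "group": "n/a", "fraction": None})
        else:
            rows += [{"source": source, "group": g, "fraction": v} for g, v in sorted(fr.items())]
    pd.DataFrame(rows).to_csv(paths["energy"], index=False)
    return paths


def plot_macros(diet: InSilicoDiet, path: str | Path) -> None:
    """Optional grouped bar chart of database vs metabolite-derived macros."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = ["carbohydrate", "protein", "lipid"]
    db_vals = [diet.macros_database.get(f"{g}_g", 0.0) for g in groups]
    met_vals = [diet.macros_metabolite.get(g, 0.0) for g in groups]
    x = range(len(groups))
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar([i - 0.2 for i in x], db_vals, width=0.4, label="database")
    ax.bar([i + 0.2 for i in x], met_vals, width=0.4, label="metabolites")
    ax.set_xticks(list(x), groups)
    ax.set_ylabel("g/day")
    ax.set_title(diet.diet_name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
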