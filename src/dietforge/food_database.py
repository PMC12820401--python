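"""Food-composition databases on a per-100 g, mmol basis.

Open food-composition resources (USDA FoodData Central, the Danish FRIDA
tables) report the chemical composition of food items as mass of nutrient
per 100 g of food.  Constraint-based metabolic models need dietary inputs in
millimoles.  This module loads long-format composition tables, harmonizes
units, converts mass measurements to mmol/100 g via molecular weights, and
stores the result as :class:`FoodDatabase` — the in-memory container every
other module consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._defaults import (
    DEFAULT_GROUP,
    DEFAULT_MACRO_NAMES,
    DEFAULT_MW,
    DEFAULT_NUTRIENT_MAP,
    KJ_PER_KCAL,
    GROUPS,
    MACRO_KEYS,
)

__all__ = [
    "FoodRecord",
    "FoodDatabase",
    "LoadReport",
    "InvalidMolecularWeightError",
    "SCHEMAS",
    "mass_to_mmol",
    "load_food_table",
    "metabolite_derived_macros",
    "read_mapping_table",
]


class InvalidMolecularWeightError(ValueError):
    """Raised when a molecular weight is zero or negative."""


#: Mass units accepted for nutrient amounts, with their factor to grams.
MASS_UNIT_TO_G: dict[str, float] = {"g": 1.0, "mg": 1e-3, "µg": 1e-6, "ug": 1e-6}

#: Energy units accepted, with their factor to kcal.
ENERGY_UNIT_TO_KCAL: dict[str, float] = {"kcal": 1.0, "kj": 1.0 / KJ_PER_KCAL}

#: Shipped schema descriptors for long-format composition tables.  Each maps
#: logical fields to column names; ``origin`` is a constant when the table
#: itself does not carry a database-origin column.
SCHEMAS: dict[str, dict[str, str]] = {
    "usda-fdc": {
        "food_id": "fdc_id",
        "description": "description",
        "nutrient": "nutrient_name",
        "amount": "amount",
        "unit": "unit_name",
        "origin": "usda",
    },
    "generic": {
        "food_id": "food_id",
        "description": "description",
        "nutrient": "nutrient_name",
        "amount": "amount",
        "unit": "unit",
        "origin_column": "origin",
    },
}


def mass_to_mmol(mass_g: float, mw: float) -> float:
    """Convert a mass per 100 g of food into mmol per 100 g.

    Parameters
    ----------
    mass_g
        Nutrient mass in grams (per 100 g of food). Must be >= 0.
    mw
        Molecular weight in g/mol. Must be > 0.

    Returns
    -------
    float
        ``mass_g / mw * 1000``, i.e. mmol per 100 g of food.
    """
    if mw <= 0 or math.isnan(mw):
        raise InvalidMolecularWeightError(f"molecular weight must be > 0, got {mw!r}")
    if mass_g < 0:
        raise ValueError(f"mass must be >= 0, got {mass_g!r}")
    return mass_g / mw * 1000.0


@dataclass
class FoodRecord:
    """One database food equivalent, everything per 100 g of the food."""

    food_id: str
    database_origin: str
    description: str
    macronutrients: dict[str, float] = field(default_factory=dict)
    metabolites: dict[str, float] = field(default_factory=dict)  # mmol / 100 g

    @property
    def key(self) -> tuple[str, str]:
        return (self.database_origin, self.food_id)

    def validate(self) -> None:
        for k, v in self.macronutrients.items():
            if k not in MACRO_KEYS:
                raise ValueError(f"unknown macronutrient key {k!r}")
            if v < 0:
                raise ValueError(f"negative macronutrient {k}={v}")
        for m, v in self.metabolites.items():
            if v < 0:
                raise ValueError(f"negative metabolite amount {m}={v}")


@dataclass
class FoodDatabase:
    """A collection of food records plus the metabolite metadata they need.

    ``molecular_weights`` (g/mol) and ``metabolite_group`` (macronutrient
    group per metabolite) must cover every metabolite identifier used by any
    record; ``validate`` enforces this.
    """

    records: dict[tuple[str, str], FoodRecord] = field(default_factory=dict)
    molecular_weights: dict[str, float] = field(default_factory=dict)
    metabolite_group: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: FoodRecord) -> None:
        record.validate()
        if record.key in self.records:
            raise ValueError(f"duplicate food record {record.key}")
        missing = [m for m in record.metabolites if m not in self.molecular_weights]
        if missing:
            raise ValueError(f"record {record.key} uses metabolites without molecular weight: {missing}")
        self.records[record.key] = record

    def get(self, origin: str, food_id: str) -> FoodRecord:
        try:
            return self.records[(origin, str(food_id))]
        except KeyError:
            raise KeyError(f"no food record ({origin!r}, {food_id!r}) in database") from None

    def group_of(self, metabolite_id: str) -> str:
        return self.metabolite_group.get(metabolite_id, "other")

    def validate(self) -> None:
        for mw in self.molecular_weights.values():
            if mw <= 0:
                raise InvalidMolecularWeightError(f"molecular weight {mw} <= 0")
        for rec in self.records.values():
            rec.validate()
            for m in rec.metabolites:
                if m not in self.molecular_weights:
                    raise ValueError(f"metabolite {m!r} lacks a molecular weight")

    # ---------------------------------------------------------------- I/O

    def to_table(self) -> pd.DataFrame:
        """Serialize to one long-format table.

        Record rows carry ``entry_type`` ``macro`` or ``metabolite``;
        metabolite metadata rows (needed to round-trip the database from a
        single file) carry ``molecular_weight`` and ``group`` with an empty
        food id.
        """
        rows: list[dict] = []
        for rec in self.records.values():
            for k, v in sorted(rec.macronutrients.items()):
                unit = "kcal" if k == "energy_kcal" else "g"
                rows.append(
                    dict(origin=rec.database_origin, food_id=rec.food_id,
                         description=rec.description, entry_type="macro",
                         key=k, value=v, unit=unit))
            for m, v in sorted(rec.metabolites.items()):
                rows.append(
                    dict(origin=rec.database_origin, food_id=rec.food_id,
                         description=rec.description, entry_type="metabolite",
                         key=m, value=v, unit="mmol"))
        for m, mw in sorted(self.molecular_weights.items()):
            rows.append(dict(origin="", food_id="", description="",
                             entry_type="molecular_weight", key=m, value=mw, unit="g/mol"))
        for m, g in sorted(self.metabolite_group.items()):
            rows.append(dict(origin="", food_id="", description="",
                             entry_type="group", key=m, value=g, unit=""))
        return pd.DataFrame(rows, columns=["origin", "food_id", "description",
                                           "entry_type", "key", "value", "unit"])

    def save(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "FoodDatabase":
        db = cls()
        meta = table[table["entry_type"].isin(["molecular_weight", "group"])]
        for _, row in meta.iterrows():
            if row["entry_type"] == "molecular_weight":
                db.molecular_weights[str(row["key"])] = float(row["value"])
            else:
                db.metabolite_group[str(row["key"])] = str(row["value"])
        body = table[table["entry_type"].isin(["macro", "metabolite"])]
        for (origin, fid), sub in body.groupby(["origin", "food_id"], sort=False):
            rec = FoodRecord(food_id=str(fid), database_origin=str(origin),
                             description=str(sub["description"].iloc[0]))
            for _, row in sub.iterrows():
                if row["entry_type"] == "macro":
                    rec.macronutrients[str(row["key"])] = float(row["value"])
                else:
                    rec.metabolites[str(row["key"])] = float(row["value"])
            db.add(rec)
        db.validate()
        return db

    @classmethod
    def load(cls, path: str | Path) -> "FoodDatabase":
        return cls.from_table(pd.read_csv(path, sep="\t", dtype={"origin": str, "food_id": str},
                                          keep_default_na=False))


@dataclass
class LoadReport:
    """Per-load log: bad rows, dropped nutrients, duplicate warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    unmapped_nutrients: dict[str, int] = field(default_factory=dict)
    n_rows: int = 0
    n_records: int = 0

    def note_unmapped(self, nutrient: str) -> None:
        self.unmapped_nutrients[nutrient] = self.unmapped_nutrients.get(nutrient, 0) + 1

    def write(self, path: str | Path) -> None:
        lines = [f"rows processed: {self.n_rows}", f"records created: {self.n_records}", ""]
        lines.append(f"errors ({len(self.errors)}):")
        lines += [f"  {e}" for e in self.errors]
        lines.append(f"warnings ({len(self.warnings)}):")
        lines += [f"  {w}" for w in self.warnings]
        lines.append("nutrients without metabolite mapping (dropped from metabolites):")
        lines += [f"  {n}: {c} rows" for n, c in sorted(self.unmapped_nutrients.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def _resolve_schema(column_map: str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(column_map, str):
        try:
            return SCHEMAS[column_map]
        except KeyError:
            raise KeyError(f"unknown schema {column_map!r}; shipped: {sorted(SCHEMAS)}") from None
    return dict(column_map)


def load_food_table(
    rows: pd.DataFrame,
    column_map: str | Mapping[str, str] = "generic",
    nutrient_map: Mapping[str, str] | None = None,
    mw_table: Mapping[str, float] | None = None,
    metabolite_group: Mapping[str, str] | None = None,
    macro_names: Mapping[str, str] | None = None,
) -> tuple[FoodDatabase, LoadReport]:
    """Build a :class:`FoodDatabase` from a long-format composition table.

    Each input row is one (food, nutrient, amount, unit) measurement per
    100 g of food.  Mass units are harmonized to grams (mg/1000, µg/1e6) and
    energy to kcal (kJ/4.184).  A nutrient whose name appears in
    ``macro_names`` populates the record's macronutrients; one with a
    metabolite mapping *and* a molecular weight becomes a mmol/100 g entry;
    anything else is counted in the report and dropped.

    Parameters
    ----------
    rows
        The composition table.
    column_map
        A shipped schema name (``"usda-fdc"``, ``"generic"``) or an explicit
        mapping of logical fields to column names.
    nutrient_map, mw_table, metabolite_group, macro_names
        Override tables; sensible small defaults ship with the package.

    Returns
    -------
    (FoodDatabase, LoadReport)
        Rows with unknown units are skipped and logged as errors; duplicate
        (origin, id, nutrient) measurements keep the first value with a
        warning.
    """
    schema = _resolve_schema(column_map)
    nmap = {k.strip().lower(): v for k, v in (nutrient_map or DEFAULT_NUTRIENT_MAP).items()}
    mws = dict(mw_table or DEFAULT_MW)
    groups = dict(metabolite_group or DEFAULT_GROUP)
    macros = {k.strip().lower(): v for k, v in (macro_names or DEFAULT_MACRO_NAMES).items()}

    db = FoodDatabase(molecular_weights=mws, metabolite_group=groups)
    report = LoadReport(n_rows=len(rows))
    seen: set[tuple[str, str, str]] = set()
    recs: dict[tuple[str, str], FoodRecord] = {}

    for idx, row in rows.iterrows():
        fid = str(row[schema["food_id"]])
        origin = (str(row[schema["origin_column"]]) if "origin_column" in schema
                  else schema["origin"])
        desc = str(row[schema["description"]])
        nutrient = str(row[schema["nutrient"]]).strip()
        unit_raw = str(row[schema["unit"]]).strip()
        unit = unit_raw.lower()
        try:
            amount = float(row[schema["amount"]])
        except (TypeError, ValueError):
            report.errors.append(f"row {idx}: non-numeric amount {row[schema['amount']]!r}")
            continue
        if amount < 0:
            report.errors.append(f"row {idx}: negative amount {amount} for {nutrient!r}")
            continue

        is_energy = unit in ENERGY_UNIT_TO_KCAL
        if unit in MASS_UNIT_TO_G:
            grams = amount * MASS_UNIT_TO_G[unit]
        elif is_energy:
            kcal = amount * ENERGY_UNIT_TO_KCAL[unit]
        else:
            report.errors.append(f"row {idx}: unknown unit {unit_raw!r} for {nutrient!r}; row skipped")
            continue

        dup_key = (origin, fid, nutrient.lower())
        if dup_key in seen:
            report.warnings.append(
                f"row {idx}: duplicate measurement ({origin}, {fid}, {nutrient}); first value kept")
            continue
        seen.add(dup_key)

        rec = recs.setdefault((origin, fid), FoodRecord(food_id=fid, database_origin=origin,
                                                        description=desc))
        nkey = nutrient.lower()
        if nkey in macros:
            macro_key = macros[nkey]
            if macro_key == "energy_kcal":
                if not is_energy:
                    report.errors.append(f"row {idx}: energy reported in mass unit {unit!r}")
                    continue
                rec.macronutrients[macro_key] = kcal
            else:
                if is_energy:
                    report.errors.append(f"row {idx}: {nutrient!r} reported in energy unit {unit!r}")
                    continue
                rec.macronutrients[macro_key] = grams
            continue
        if is_energy:
            report.errors.append(f"row {idx}: energy unit {unit!r} on non-energy nutrient {nutrient!r}")
            continue
        met = nmap.get(nkey)
        if met is None:
            report.note_unmapped(nutrient)
            continue
        if met not in mws:
            report.warnings.append(
                f"row {idx}: metabolite {met!r} has no molecular weight; excluded from mmol conversion")
            continue
        rec.metabolites[met] = mass_to_mmol(grams, mws[met])

    for rec in recs.values():
        db.add(rec)
    report.n_records = len(db)
    return db, report


def metabolite_derived_macros(record: FoodRecord, db: FoodDatabase) -> dict[str, float]:
    """Macronutrient masses (g/100 g) implied by a record's measured metabolites.

    Sums ``mmol/100g × MW / 1000`` over the metabolites of each macronutrient
    group.  Metabolites with no group assignment count toward ``"other"``.
    Groups with no members map to 0.
    """
    out = {g: 0.0 for g in GROUPS}
    for met, mmol in record.metabolites.items():
        mw = db.molecular_weights.get(met)
        if mw is None:
            raise KeyError(f"metabolite {met!r} lacks a molecular weight")
        out[db.group_of(met)] = out.get(db.group_of(met), 0.0) + mmol * mw / 1000.0
    return out


def read_mapping_table(path: str | Path, value_type: type = str) -> dict:
    """Read a two-column key/value TSV (nutrient map, molecular weights, groups)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    return {str(k): value_type(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def _iter_records(db: FoodDatabase) -> Iterable[FoodRecord]:
    return db.records.values()
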