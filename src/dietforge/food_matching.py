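"""Match user-described dietary food items to database food equivalents.

A dietary food item (one row of the food-description file a user fills in
from labels or food-frequency questionnaires) carries keywords, a reference
weight, and whatever macronutrients the user knows.  Matching proceeds in
two steps: keyword search over record descriptions, then scoring of the
hits by Euclidean distance between macronutrient profiles rescaled to a
common per-100 g basis.  Total carbohydrate never enters the distance —
databases and labels disagree on whether fibre is part of it — only the
unambiguous components sugars, fibre and starch do.  Alongside the distance
each candidate reports, per macronutrient group, what percentage of its
reported macro mass is actually accounted for by individually measured
metabolites; a candidate slightly farther in macro space may be preferable
if its metabolite coverage is higher, because only measured metabolites
reach the metabolic model.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._defaults import DISTANCE_KEYS, GROUPS
from .food_database import FoodDatabase, FoodRecord, metabolite_derived_macros

__all__ = [
    "DietaryFoodItem",
    "CandidateScore",
    "ItemReport",
    "MatchReport",
    "DEFAULT_HIT_CAP",
    "DEFAULT_TOP_N",
    "search_candidates",
    "macro_distance",
    "coverage_percent",
    "score_item",
    "match_items",
    "write_reports",
    "read_food_description",
]

#: Items yielding more keyword hits than this are diverted to the
#: too-many-hits report for keyword refinement instead of being scored.
DEFAULT_HIT_CAP: int = 50

#: Number of rows per item in the short-form comparison report.
DEFAULT_TOP_N: int = 10


@dataclass
class DietaryFoodItem:
    """A food as the user describes it, macros given per ``reference_weight_g``."""

    name: str
    keywords: list[str]
    reference_weight_g: float = 100.0
    user_macros: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_weight_g <= 0:
            raise ValueError(f"{self.name!r}: reference weight must be > 0")
        if not self.keywords:
            raise ValueError(f"{self.name!r}: at least one keyword is required")
        for kw in self.keywords:
            if re.search(r"[;,\s]", kw):
                raise ValueError(f"{self.name!r}: keyword {kw!r} must be a single word")
        bad = set(self.user_macros) - set(DISTANCE_KEYS)
        if bad:
            raise ValueError(f"{self.name!r}: unsupported macro fields {sorted(bad)}; "
                             f"allowed: {list(DISTANCE_KEYS)}")
        for k, v in self.user_macros.items():
            if v < 0:
                raise ValueError(f"{self.name!r}: negative macro {k}={v}")

    def macros_per_100g(self) -> dict[str, float]:
        """User macros rescaled from the reference weight to per 100 g."""
        f = 100.0 / self.reference_weight_g
        return {k: v * f for k, v in self.user_macros.items()}


@dataclass
class CandidateScore:
    """One scored database food equivalent for one dietary food item."""

    candidate: tuple[str, str]  # (database_origin, food_id)
    distance: float | None  # None when the user supplied no macros
    coverage: dict[str, float | None] = field(default_factory=dict)  # percent; None = n/a
    missing_macros: list[str] = field(default_factory=list)  # distance fields absent from record

    def mean_coverage(self) -> float:
        vals = [v for v in self.coverage.values() if v is not None]
        return sum(vals) / len(vals) if vals else 0.0


@dataclass
class ItemReport:
    """Search + scoring outcome for one dietary food item."""

    item: DietaryFoodItem
    status: str  # "ok" | "no_hits" | "too_many_hits"
    candidates: list[CandidateScore] = field(default_factory=list)  # status ok, ranked
    raw_hits: list[tuple[str, str]] = field(default_factory=list)  # status too_many_hits
    skipped_keywords: list[str] = field(default_factory=list)  # sequential-strategy skips


@dataclass
class MatchReport:
    """All per-item reports of one matching run."""

    items: list[ItemReport] = field(default_factory=list)

    def by_name(self, name: str) -> ItemReport:
        for rep in self.items:
            if rep.item.name == name:
                return rep
        raise KeyError(name)


_PUNCT = re.compile(r"[^\w]+")


def _normalize(text: str) -> str:
    # lower-case, collapse punctuation to spaces so keyword substrings do not
    # straddle separators awkwardly; no stemming
    return _PUNCT.sub(" ", text.lower())


def search_candidates(
    item: DietaryFoodItem,
    db: FoodDatabase,
    strategy: str = "cumulative",
    cap: int = DEFAULT_HIT_CAP,
) -> ItemReport:
    """Keyword search for database food equivalents of one dietary item.

    Matching is case-insensitive substring search of each keyword against
    the record description.  ``cumulative`` requires every keyword to occur.
    ``sequential`` applies keywords in order, each narrowing the surviving
    set; a keyword that would empty the set is skipped (and logged), so an
    over-specific trailing keyword cannot wipe out good hits from the
    leading, most descriptive one.

    Zero hits gives status ``no_hits``; more than ``cap`` hits gives
    ``too_many_hits`` with the full hit list for keyword refinement.
    """
    if strategy not in ("cumulative", "sequential"):
        raise ValueError(f"unknown search strategy {strategy!r}")
    if not db.records:
        raise ValueError("food database is empty")
    if cap < 1:
        raise ValueError("hit cap must be a positive integer")

    keywords = [kw.lower() for kw in item.keywords]
    descs = {key: _normalize(rec.description) for key, rec in db.records.items()}
    skipped: list[str] = []

    if strategy == "cumulative":
        hits = [key for key, d in descs.items() if all(kw in d for kw in keywords)]
    else:
        survivors = list(descs)
        for kw in keywords:
            narrowed = [key for key in survivors if kw in descs[key]]
            if narrowed:
                survivors = narrowed
            else:
                skipped.append(kw)
        # if even the first keyword matched nothing, every keyword was
        # skipped and the unfiltered set must not count as a hit list
        hits = survivors if len(skipped) < len(keywords) else []

    hits.sort()
    if not hits:
        return ItemReport(item=item, status="no_hits", skipped_keywords=skipped)
    if len(hits) > cap:
        return ItemReport(item=item, status="too_many_hits", raw_hits=hits,
                          skipped_keywords=skipped)
    return ItemReport(item=item, status="ok",
                      candidates=[CandidateScore(candidate=key, distance=None) for key in hits],
                      skipped_keywords=skipped)


def macro_distance(item: DietaryFoodItem, record: FoodRecord) -> tuple[float | None, list[str]]:
    """Euclidean distance between user and record macros on a per-100 g basis.

    Only the fields the user supplied enter the norm, drawn from energy,
    lipid, protein, sugars, fibre and starch; total carbohydrate never does.
    A supplied field missing from the record counts as 0 and is returned in
    the flag list.  With no user macros the distance is undefined (``None``)
    and the candidate is ranked by coverage alone.
    """
    user = item.macros_per_100g()
    if not user:
        return None, []
    missing = [k for k in user if k not in record.macronutrients]
    sq = 0.0
    for k, v in user.items():
        sq += (v - record.macronutrients.get(k, 0.0)) ** 2
    return math.sqrt(sq), missing


def coverage_percent(record: FoodRecord, db: FoodDatabase) -> dict[str, float | None]:
    """Percent of each reported macro mass accounted for by measured metabolites.

    For each macronutrient group with a reported database macro > 0 the value
    is ``100 × metabolite-derived mass / reported mass``; it may exceed 100
    when measured metabolites outweigh the reported macro.  A group whose
    reported macro is 0 or absent is not applicable (``None``).  The reported
    carbohydrate mass is the record's total carbohydrate when present,
    otherwise the sum of its reported sugars, fibre and starch.
    """
    derived = metabolite_derived_macros(record, db)
    reported: dict[str, float | None] = {
        "protein": record.macronutrients.get("protein_g"),
        "lipid": record.macronutrients.get("lipid_g"),
    }
    if "carbohydrate_g" in record.macronutrients:
        reported["carbohydrate"] = record.macronutrients["carbohydrate_g"]
    else:
        parts = [record.macronutrients.get(k) for k in ("sugars_g", "fibre_g", "starch_g")]
        known = [p for p in parts if p is not None]
        reported["carbohydrate"] = sum(known) if known else None
    out: dict[str, float | None] = {}
    for group in GROUPS:
        if group == "other":
            continue
        ref = reported.get(group)
        out[group] = None if not ref else 100.0 * derived[group] / ref
    return out


def score_item(report: ItemReport, db: FoodDatabase) -> ItemReport:
    """Fill in distance and coverage for an ok-status report and rank it.

    Ranking: distance ascending (undefined distances last), then mean
    coverage descending, then food id ascending — a deterministic total
    order.
    """
    if report.status != "ok":
        return report
    for cand in report.candidates:
        rec = db.records[cand.candidate]
        cand.distance, cand.missing_macros = macro_distance(report.item, rec)
        cand.coverage = coverage_percent(rec, db)
    report.candidates.sort(
        key=lambda c: (c.distance is None, c.distance if c.distance is not None else 0.0,
                       -c.mean_coverage(), c.candidate[1]))
    return report


def match_items(
    items: Iterable[DietaryFoodItem],
    db: FoodDatabase,
    strategy: str = "cumulative",
    cap: int = DEFAULT_HIT_CAP,
) -> MatchReport:
    """Search and score every dietary food item against the database."""
    return MatchReport(items=[score_item(search_candidates(i, db, strategy, cap), db)
                              for i in items])


def _comparison_frame(reports: MatchReport, db: FoodDatabase, top_n: int | None) -> pd.DataFrame:
    rows = []
    for rep in reports.items:
        if rep.status != "ok":
            continue
        cands = rep.candidates if top_n is None else rep.candidates[:top_n]
        for rank, c in enumerate(cands, start=1):
            rec = db.records[c.candidate]
            row = {
                "OriginalFood": rep.item.name,
                "rank": rank,
                "databaseOrigin": c.candidate[0],
                "databaseID": c.candidate[1],
                "description": rec.description,
                "distance": c.distance,
                "missing_macros": ";".join(c.missing_macros),
            }
            for g in ("carbohydrate", "protein", "lipid"):
                row[f"coverage_{g}_pct"] = c.coverage.get(g)
            for k in DISTANCE_KEYS:
                row[f"db_{k}"] = rec.macronutrients.get(k)
            rows.append(row)
    return pd.DataFrame(rows)


def write_reports(
    reports: MatchReport,
    out_dir: str | Path,
    db: FoodDatabase,
    top_n: int = DEFAULT_TOP_N,
) -> dict[str, Path]:
    """Write the four matching artifacts into ``out_dir``.

    ``fullComparisonFoodItems.csv`` lists every scored candidate,
    ``topResultsComparisonFoodItems.csv`` the best ``top_n`` per item,
    ``noDatabaseHits.txt`` the items whose keywords matched nothing, and
    ``tooManyDatabaseHits.csv`` the raw hit lists of items exceeding the cap.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "full": out / "fullComparisonFoodItems.csv",
        "top": out / "topResultsComparisonFoodItems.csv",
        "no_hits": out / "noDatabaseHits.txt",
        "too_many": out / "tooManyDatabaseHits.csv",
    }
    _comparison_frame(reports, db, None).to_csv(paths["full"], index=False)
    _comparison_frame(reports, db, top_n).to_csv(paths["top"], index=False)

    no_hits = [rep.item.name for rep in reports.items if rep.status == "no_hits"]
    paths["no_hits"].write_text("\n".join(no_hits) + ("\n" if no_hits else ""))

    tm_rows = [
        {"OriginalFood": rep.item.name, "databaseOrigin": origin, "databaseID": fid,
         "description": db.records[(origin, fid)].description}
        for rep in reports.items if rep.status == "too_many_hits"
        for origin, fid in rep.raw_hits
    ]
    pd.DataFrame(tm_rows, columns=["OriginalFood", "databaseOrigin", "databaseID",
                                   "description"]).to_csv(paths["too_many"], index=False)
    return paths


#: Column header of the food-description file -> (attribute, macro key).
_FOOD_DESC_MACROS: dict[str, str] = {
    "Energy (kcal)": "energy_kcal",
    "Lipid (g)": "lipid_g",
    "Protein (g)": "protein_g",
    "Sugars (g)": "sugars_g",
    "Fibre (g)": "fibre_g",
    "Starch (g)": "starch_g",
}


def read_food_description(path: str | Path) -> list[DietaryFoodItem]:
    """Read a food-description CSV.

    Expected header: ``OriginalFood, KeyWords, ReferenceWeight(g)`` followed
    by any of ``Energy (kcal), Lipid (g), Protein (g), Sugars (g), Fibre
    (g), Starch (g)``.  Keywords are semicolon-separated inside one cell;
    macro cells may be left blank.
    """
    df = pd.read_csv(path)
    required = {"OriginalFood", "KeyWords", "ReferenceWeight(g)"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    items = []
    for _, row in df.iterrows():
        keywords = [kw.strip() for kw in str(row["KeyWords"]).split(";") if kw.strip()]
        macros = {}
        for col, key in _FOOD_DESC_MACROS.items():
            if col in df.columns and pd.notna(row[col]):
                macros[key] = float(row[col])
        items.append(DietaryFoodItem(
            name=str(row["OriginalFood"]).strip(),
            keywords=keywords,
            reference_weight_g=float(row["ReferenceWeight(g)"]),
            user_macros=macros,
        ))
    return items
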