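"""Keyword search, macro distance, coverage and report tests."""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietforge.fixtures import FixtureSpec, make_toy_food_db
from dietforge.food_database import FoodDatabase, FoodRecord
from dietforge.food_matching import (
    DietaryFoodItem,
    coverage_percent,
    macro_distance,
    match_items,
    read_food_description,
    score_item,
    search_candidates,
    write_reports,
)


@pytest.fixture(scope="module")
def mini_db():
    db = FoodDatabase(molecular_weights={"glc_D": 180.156},
                      metabolite_group={"glc_D": "carbohydrate"})
    for fid, desc in [("1", "Apple, red, raw"), ("2", "Apple pie"), ("3", "Red cabbage")]:
        db.add(FoodRecord(fid, "usda", desc, macronutrients={"energy_kcal": 50.0}))
    return db


def item(keywords, **macros):
    return DietaryFoodItem(name="test", keywords=keywords, reference_weight_g=100.0,
                           user_macros=macros)


class TestSearch:
    def test_cumulative_requires_every_keyword(self, mini_db):
        rep = search_candidates(item(["apple", "red"]), mini_db, "cumulative")
        assert rep.status == "ok"
        assert [c.candidate for c in rep.candidates] == [("usda", "1")]

    def test_sequential_narrows_in_order(self, mini_db):
        rep = search_candidates(item(["apple", "red"]), mini_db, "sequential")
        assert rep.status == "ok"
        assert [c.candidate for c in rep.candidates] == [("usda", "1")]
        assert rep.skipped_keywords == []

    def test_sequential_skips_keyword_that_would_empty_the_set(self, mini_db):
        rep = search_candidates(item(["apple", "zucchini", "red"]), mini_db, "sequential")
        assert rep.status == "ok"
        assert rep.skipped_keywords == ["zucchini"]
        assert [c.candidate for c in rep.candidates] == [("usda", "1")]

    def test_unmatched_keyword_gives_no_hits_cumulative(self, mini_db):
        assert search_candidates(item(["zucchini"]), mini_db).status == "no_hits"

    def test_hits_above_cap_diverted(self):
        db = make_toy_food_db(FixtureSpec(seed=3, n_apple_hits=51))
        rep = search_candidates(item(["apple"]), db)
        assert rep.status == "too_many_hits"
        assert len(rep.raw_hits) == 51

    def test_hits_at_cap_pass(self):
        db = make_toy_food_db(FixtureSpec(seed=3, n_apple_hits=50))
        rep = search_candidates(item(["apple"]), db)
        assert rep.status == "ok"
        assert len(rep.candidates) == 50

    def test_cumulative_is_subset_of_any_keyword_prefix(self):
        db = make_toy_food_db(FixtureSpec(seed=5, n_foods=40))
        kws = ["a", "e", "raw"]
        full = {c.candidate for c in
                search_candidates(item(kws), db, cap=10_000).candidates}
        for n in range(1, len(kws)):
            rep = search_candidates(item(kws[:n]), db, cap=10_000)
            prefix = {c.candidate for c in rep.candidates}
            assert full <= prefix

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            DietaryFoodItem(name="x", keywords=[], reference_weight_g=100.0)

    def test_multiword_keyword_rejected(self):
        with pytest.raises(ValueError):
            DietaryFoodItem(name="x", keywords=["red apple"], reference_weight_g=100.0)


class TestMacroDistance:
    def test_identical_profiles_have_zero_distance(self, mini_db):
        rec = FoodRecord("9", "usda", "x",
                         macronutrients={"energy_kcal": 50.0, "protein_g": 2.0})
        it = item(["x"], energy_kcal=50.0, protein_g=2.0)
        dist, missing = macro_distance(it, rec)
        assert dist == 0.0 and missing == []

    def test_pythagorean_example(self):
        rec = FoodRecord("9", "usda", "x",
                         macronutrients={"energy_kcal": 1.0, "protein_g": 6.0})
        it = item(["x"], energy_kcal=4.0, protein_g=2.0)
        dist, _ = macro_distance(it, rec)
        assert dist == pytest.approx(5.0)

    def test_red_apple_matches_its_own_record(self, toy_db):
        """The worked-example item (per 150 g) is distance 0 from its record."""
        it = DietaryFoodItem(name="Red apple", keywords=["Apple", "Red"],
                             reference_weight_g=150.0,
                             user_macros={"energy_kcal": 91.4, "lipid_g": 0.1,
                                          "protein_g": 0.4, "sugars_g": 15.5})
        dist, missing = macro_distance(it, toy_db.get("usda", "1105430"))
        assert dist == pytest.approx(0.0, abs=1e-12)
        assert missing == []

    @settings(max_examples=50, derandomize=True)
    @given(weight=st.floats(10.0, 1000.0))
    def test_reference_weight_invariance(self, weight):
        """Describing the same food per any reference weight gives one distance."""
        rec = FoodRecord("9", "usda", "x",
                         macronutrients={"energy_kcal": 60.0, "sugars_g": 9.0})
        base = item(["x"], energy_kcal=90.0, sugars_g=12.0)
        scaled = DietaryFoodItem(
            name="y", keywords=["x"], reference_weight_g=weight,
            user_macros={k: v * weight / 100.0 for k, v in base.user_macros.items()})
        assert macro_distance(scaled, rec)[0] == pytest.approx(
            macro_distance(base, rec)[0], rel=1e-12)

    def test_unsupplied_record_macro_does_not_enter(self):
        bare = FoodRecord("9", "usda", "x", macronutrients={"energy_kcal": 10.0})
        rich = FoodRecord("9", "usda", "x",
                          macronutrients={"energy_kcal": 10.0, "starch_g": 40.0})
        it = item(["x"], energy_kcal=12.0)
        assert macro_distance(it, bare)[0] == macro_distance(it, rich)[0]

    def test_supplying_one_more_field_never_decreases_distance(self):
        rec = FoodRecord("9", "usda", "x",
                         macronutrients={"energy_kcal": 10.0, "protein_g": 1.0})
        d1 = macro_distance(item(["x"], energy_kcal=12.0), rec)[0]
        d2 = macro_distance(item(["x"], energy_kcal=12.0, protein_g=4.0), rec)[0]
        assert d2 >= d1

    def test_missing_record_macro_counts_as_zero_and_is_flagged(self):
        rec = FoodRecord("9", "usda", "x", macronutrients={"energy_kcal": 10.0})
        dist, missing = macro_distance(item(["x"], energy_kcal=10.0, fibre_g=3.0), rec)
        assert dist == pytest.approx(3.0)
        assert missing == ["fibre_g"]

    def test_no_user_macros_distance_undefined(self):
        rec = FoodRecord("9", "usda", "x", macronutrients={"energy_kcal": 10.0})
        dist, _ = macro_distance(item(["x"]), rec)
        assert dist is None

    def test_total_carbohydrate_is_not_an_accepted_field(self):
        with pytest.raises(ValueError):
            item(["x"], carbohydrate_g=10.0)


class TestCoverage:
    def test_planted_eighty_percent_protein(self, toy_db):
        cov = coverage_percent(toy_db.get("usda", "900001"), toy_db)
        assert cov["protein"] == pytest.approx(80.0, rel=1e-9)

    def test_full_coverage_reads_one_hundred(self, toy_db):
        from dietforge.food_database import mass_to_mmol
        rec = FoodRecord("x", "usda", "t",
                         macronutrients={"lipid_g": 5.0},
                         metabolites={"lnlc": mass_to_mmol(5.0, 280.446)})
        assert coverage_percent(rec, toy_db)["lipid"] == pytest.approx(100.0, rel=1e-9)

    def test_no_metabolites_zero_or_not_applicable(self, toy_db):
        rec = FoodRecord("x", "usda", "t", macronutrients={"protein_g": 4.0})
        cov = coverage_percent(rec, toy_db)
        assert cov["protein"] == 0.0
        assert cov["lipid"] is None  # no reported lipid -> n/a

    def test_carbohydrate_reference_falls_back_to_components(self, toy_db):
        from dietforge.food_database import mass_to_mmol
        rec = FoodRecord("x", "usda", "t",
                         macronutrients={"sugars_g": 6.0, "starch_g": 4.0},
                         metabolites={"glc_D": mass_to_mmol(5.0, 180.156)})
        assert coverage_percent(rec, toy_db)["carbohydrate"] == pytest.approx(50.0)


class TestReports:
    def test_top_report_truncates_to_ten(self, tmp_path):
        db = make_toy_food_db(FixtureSpec(seed=3, n_apple_hits=25))
        reports = match_items([item(["apple"], energy_kcal=52.0)], db)
        paths = write_reports(reports, tmp_path, db)
        assert len(pd.read_csv(paths["full"])) == 25
        assert len(pd.read_csv(paths["top"])) == 10

    def test_small_hit_list_appears_in_both_reports(self, mini_db, tmp_path):
        reports = match_items([item(["apple"], energy_kcal=52.0)], mini_db)
        paths = write_reports(reports, tmp_path, mini_db)
        assert len(pd.read_csv(paths["full"])) == 2
        assert len(pd.read_csv(paths["top"])) == 2

    def test_no_hits_and_too_many_hits_files(self, tmp_path):
        db = make_toy_food_db(FixtureSpec(seed=3, n_apple_hits=51))
        reports = match_items([item(["zzz"]), item(["apple"])], db)
        paths = write_reports(reports, tmp_path, db)
        assert paths["no_hits"].read_text().strip() == "test"
        assert len(pd.read_csv(paths["too_many"])) == 51

    def test_equal_distance_ties_broken_by_coverage_then_id(self, toy_db):
        rep = search_candidates(item(["a"], energy_kcal=52.0), toy_db, cap=10_000)
        rep = score_item(rep, toy_db)
        ranked = rep.candidates
        for prev, nxt in zip(ranked, ranked[1:]):
            key_prev = (prev.distance, -prev.mean_coverage(), prev.candidate[1])
            key_nxt = (nxt.distance, -nxt.mean_coverage(), nxt.candidate[1])
            assert key_prev <= key_nxt


class TestFoodDescriptionIO:
    def test_reads_keywords_and_partial_macros(self, tmp_path):
        p = tmp_path / "foods.csv"
        p.write_text(
            "OriginalFood,KeyWords,ReferenceWeight(g),Energy (kcal),Lipid (g),"
            "Protein (g),Sugars (g)\n"
            "Red apple,Apple; Red,150,91.4,0.1,0.4,15.5\n"
            "Mystery,Thing,80,,,,\n")
        items = read_food_description(p)
        assert items[0].keywords == ["Apple", "Red"]
        assert items[0].user_macros == {"energy_kcal": 91.4, "lipid_g": 0.1,
                                        "protein_g": 0.4, "sugars_g": 15.5}
        assert items[1].user_macros == {}
        assert items[1].reference_weight_g == 80.0
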