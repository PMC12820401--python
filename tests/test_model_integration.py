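"""Constraining models with diets, the food-item formulation, feasibility."""

from __future__ import annotations

import numpy as np
import pytest

from dietforge.diet_builder import ConsumedRow, EquivalentsConsumed, build_diet, InSilicoDiet
from dietforge.fixtures import (
    ESSENTIAL_CANDIDATES,
    FixtureSpec,
    make_toy_food_db,
    make_toy_wbm,
    table2_equivalents_consumed,
)
from dietforge.model_integration import (
    add_food_reactions,
    apply_diet,
    apply_food_diet,
    check_feasibility,
    diet_to_constraints,
    food_breakdown_id,
    food_exchange_id,
    macro_sink_id,
    maximize_reaction,
    restore_feasibility,
)


class TestDietToConstraints:
    def test_uptake_bounds_are_minus_flux_to_zero(self):
        diet = InSilicoDiet("d", flux={"glc_D": 30.0})
        cons, skipped = diet_to_constraints(diet)
        assert cons == {"Diet_EX_glc_D[d]": (-30.0, 0.0)}
        assert skipped == []

    def test_enforce_fraction_one_forces_uptake(self):
        diet = InSilicoDiet("d", flux={"glc_D": 30.0})
        cons, _ = diet_to_constraints(diet, enforce_fraction=1.0)
        assert cons["Diet_EX_glc_D[d]"] == (-30.0, -30.0)

    def test_empty_diet_empty_constraints(self):
        assert diet_to_constraints(InSilicoDiet("d")) == ({}, [])

    def test_metabolites_without_model_exchange_are_skipped(self, toy_model):
        diet = InSilicoDiet("d", flux={"glc_D": 5.0, "unobtainium": 1.0})
        cons, skipped = diet_to_constraints(diet, toy_model)
        assert "Diet_EX_glc_D[d]" in cons
        assert skipped == ["unobtainium"]


class TestApplyDiet:
    def test_bounds_overwritten_exactly_and_idempotently(self, toy_model, toy_db, equivalents):
        diet = build_diet(equivalents, toy_db, "diet1")
        cons, _ = diet_to_constraints(diet, toy_model)
        apply_diet(toy_model, cons)
        first = {r.id: r.bounds for r in toy_model.reactions}
        apply_diet(toy_model, cons)
        assert {r.id: r.bounds for r in toy_model.reactions} == first
        for rxn_id, bounds in cons.items():
            assert toy_model.reactions.get_by_id(rxn_id).bounds == bounds

    def test_unlisted_diet_exchanges_are_closed(self, toy_model):
        diet = InSilicoDiet("d", flux={"glc_D": 5.0})
        cons, _ = diet_to_constraints(diet, toy_model)
        apply_diet(toy_model, cons)
        assert toy_model.reactions.get_by_id("Diet_EX_thm[d]").bounds == (0.0, 0.0)

    def test_stoichiometry_untouched(self, toy_model, toy_db, equivalents):
        diet = build_diet(equivalents, toy_db, "diet1")
        n_rxns, n_mets = len(toy_model.reactions), len(toy_model.metabolites)
        cons, _ = diet_to_constraints(diet, toy_model)
        apply_diet(toy_model, cons)
        assert (len(toy_model.reactions), len(toy_model.metabolites)) == (n_rxns, n_mets)

    def test_unknown_reaction_id_raises(self, toy_model):
        with pytest.raises(KeyError):
            apply_diet(toy_model, {"Diet_EX_bogus[d]": (-1.0, 0.0)})


class TestFoodReactions:
    def test_breakdown_coefficients_are_per_gram(self, toy_model, toy_db):
        add_food_reactions(toy_model, toy_db, [("usda", "168191")])
        bd = toy_model.reactions.get_by_id(food_breakdown_id("usda", "168191"))
        rec = toy_db.get("usda", "168191")
        met = toy_model.metabolites.get_by_id("glc_D[d]")
        assert bd.metabolites[met] == pytest.approx(rec.metabolites["glc_D"] / 100.0)
        macro = toy_model.metabolites.get_by_id("energy_kcal[d]")
        assert bd.metabolites[macro] == pytest.approx(
            rec.macronutrients["energy_kcal"] / 100.0)

    def test_duplicate_addition_rejected(self, toy_model, toy_db):
        add_food_reactions(toy_model, toy_db, [("usda", "168191")])
        with pytest.raises(ValueError, match="already present"):
            add_food_reactions(toy_model, toy_db, [("usda", "168191")])

    def test_record_without_metabolites_breaks_down_to_macros_only(self, toy_model, toy_db):
        from dietforge.food_database import FoodRecord
        db = make_toy_food_db(FixtureSpec(seed=1))
        db.add(FoodRecord("990", "usda", "Pure energy", macronutrients={"energy_kcal": 100.0}))
        add_food_reactions(toy_model, db, [("usda", "990")])
        bd = toy_model.reactions.get_by_id(food_breakdown_id("usda", "990"))
        products = [m.id for m, c in bd.metabolites.items() if c > 0]
        assert products == ["energy_kcal[d]"]

    def test_macro_pseudometabolites_touch_only_breakdown_and_sink(self, toy_model, toy_db, equivalents):
        items = sorted(equivalents.consumption("diet1"))
        add_food_reactions(toy_model, toy_db, items)
        for met in toy_model.metabolites:
            if not met.id.endswith("_g[d]") and not met.id.startswith("energy_kcal"):
                continue
            for rxn in met.reactions:
                assert (rxn.id.startswith("Food_BD_")
                        or rxn.id == macro_sink_id(met.id.removesuffix("[d]")))

    def test_fixed_food_grams_reproduce_build_diet_availability(self, toy_model, toy_db):
        """Forcing 150 g through a food exchange delivers exactly the
        metabolite amounts the diet builder computes for 150 g."""
        add_food_reactions(toy_model, toy_db, [("usda", "168191")])
        apply_food_diet(toy_model, {("usda", "168191"): 150.0}, enforce_fraction=1.0)
        rec = toy_db.get("usda", "168191")
        with toy_model:
            toy_model.objective = toy_model.reactions.get_by_id(
                food_breakdown_id("usda", "168191"))
            sol = toy_model.optimize()
        assert sol.fluxes[food_breakdown_id("usda", "168191")] == pytest.approx(150.0)
        for met, per100 in rec.metabolites.items():
            produced = sol.fluxes[food_breakdown_id("usda", "168191")] * per100 / 100.0
            assert produced == pytest.approx(per100 / 100.0 * 150.0)


class TestEquivalence:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_metabolite_and_food_constrained_optima_agree(self, toy_db, seed):
        """FBA optima agree between diet-exchange bounds and fixed food grams."""
        rng = np.random.default_rng(seed)
        items = [("usda", "168191"), ("usda", "1105430"), ("frida", "1215"),
                 ("usda", "900002")]
        grams = {item: float(rng.uniform(0.0, 120.0)) for item in items}
        eq = EquivalentsConsumed(rows=[
            ConsumedRow(i[1], i[1], i[0], {"d": g}) for i, g in grams.items()])
        diet = build_diet(eq, toy_db, "d")

        m_met = make_toy_wbm()
        cons, _ = diet_to_constraints(diet, m_met)
        apply_diet(m_met, cons)
        opt_met = check_feasibility(m_met, required_objective=0.0).objective_value

        m_food = make_toy_wbm()
        add_food_reactions(m_food, toy_db, items)
        apply_food_diet(m_food, grams, enforce_fraction=1.0)
        opt_food = check_feasibility(m_food, required_objective=0.0).objective_value
        assert opt_food == pytest.approx(opt_met, abs=1e-6)


class TestFeasibility:
    def test_adequate_diet_is_feasible(self, toy_model, toy_db, equivalents):
        diet = build_diet(equivalents, toy_db, "diet1")
        apply_diet(toy_model, diet_to_constraints(diet, toy_model)[0])
        res = check_feasibility(toy_model)
        assert res.feasible and res.objective_value >= 1.0

    def test_closed_diet_is_infeasible(self, toy_model):
        apply_diet(toy_model, {})
        res = check_feasibility(toy_model)
        assert not res.feasible

    def test_required_objective_zero_always_satisfiable(self, toy_model):
        apply_diet(toy_model, {})
        assert check_feasibility(toy_model, required_objective=0.0).feasible

    def test_target_maximum_matches_closed_form(self, toy_model, toy_db, equivalents):
        """Serotonin synthesis consumes 2 trp, so its ceiling is uptake / 2."""
        diet = build_diet(equivalents, toy_db, "diet1")
        apply_diet(toy_model, diet_to_constraints(diet, toy_model)[0])
        assert maximize_reaction(toy_model, "SRTN_SYN") == pytest.approx(
            diet.flux["trp_L"] / 2.0)


class TestRestoreFeasibility:
    def make_defective(self, defect_db):
        diet = build_diet(table2_equivalents_consumed(), defect_db, "diet1")
        model = make_toy_wbm()
        apply_diet(model, diet_to_constraints(diet, model)[0])
        return model, diet

    def test_single_planted_adjustment_restores(self, defect_db):
        model, diet = self.make_defective(defect_db)
        assert not check_feasibility(model).feasible
        result, adjusted = restore_feasibility(model, diet, ESSENTIAL_CANDIDATES)
        assert result.feasible
        assert result.adjustments == [("thm", 0.05)]
        assert adjusted.flux["thm"] == pytest.approx(0.05)

    def test_repair_never_reduces_any_uptake(self, defect_db):
        model, diet = self.make_defective(defect_db)
        before = {r.id: r.bounds for r in model.reactions}
        restore_feasibility(model, diet, ESSENTIAL_CANDIDATES)
        for rxn in model.reactions:
            lb0, ub0 = before[rxn.id]
            assert rxn.lower_bound <= lb0 + 1e-12  # only ever relaxed downward
            assert rxn.upper_bound == ub0

    def test_feasible_input_returns_unchanged_diet(self, toy_db, toy_model, equivalents):
        diet = build_diet(equivalents, toy_db, "diet1")
        apply_diet(toy_model, diet_to_constraints(diet, toy_model)[0])
        result, adjusted = restore_feasibility(toy_model, diet, ESSENTIAL_CANDIDATES)
        assert result.feasible and result.adjustments == []
        assert adjusted.flux == diet.flux

    def test_empty_candidate_list_stays_infeasible(self, defect_db):
        model, diet = self.make_defective(defect_db)
        result, adjusted = restore_feasibility(model, diet, [])
        assert not result.feasible and result.adjustments == []
        assert adjusted.flux == diet.flux


class TestModelIO:
    def test_sbml_round_trip_preserves_optimum(self, toy_model, toy_db, equivalents, tmp_path):
        import cobra.io

        diet = build_diet(equivalents, toy_db, "diet1")
        apply_diet(toy_model, diet_to_constraints(diet, toy_model)[0])
        opt = check_feasibility(toy_model).objective_value
        path = tmp_path / "m.xml"
        cobra.io.write_sbml_model(toy_model, str(path))
        loaded = cobra.io.read_sbml_model(str(path))
        assert check_feasibility(loaded).objective_value == pytest.approx(opt, abs=1e-9)
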