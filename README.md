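# dietforge

**Metabolite-resolved *in silico* diets for constraint-based metabolic models.**

Constraint-based models of human metabolism — up to organ-resolved
whole-body models (WBMs) — take their dietary input as flux bounds on
exchange reactions, in mmol per day per metabolite. People, food labels and
food-frequency questionnaires describe diets as *food items* in grams.
`dietforge` bridges the two: it normalizes food-composition tables (USDA
FoodData Central / FRIDA-style schemas) to a per-100 g mmol basis, matches
user-described foods to database equivalents, compiles consumed weights into
metabolite flux vectors, applies them to COBRA models, and computes minimal
dietary changes that optimize target metabolic fluxes. It is aimed at
researchers in metabolic modelling and computational nutrition.

## What it computes

**Composition normalization.** A nutrient measured as mass per 100 g of
food becomes millimoles via its molecular weight,
`mmol/100 g = mass_g / MW × 1000`, with units harmonized first
(mg → /10³, µg → /10⁶, kJ → kcal via 4.184).

**Food matching.** Candidate database equivalents are found by keyword
substring search (cumulative AND, or sequential narrowing with skip) and
scored by the Euclidean distance between macronutrient profiles rescaled to
per-100 g. Total carbohydrate never enters the distance — databases
disagree on whether fibre is included — only sugars, fibre and starch do.
Each candidate also reports, per macronutrient group, the percentage of its
reported macro mass accounted for by individually measured metabolites
(only measured metabolites reach the model).

**Diet compilation.** For each consumed food,
`flux_m = Σ_foods (mmol_m /100 g) / 100 × grams`, giving mmol/day/person
per metabolite, plus macronutrient and Atwater energy-fraction summaries
computed twice: from database-reported macros and from the measured
metabolites themselves.

**Model integration.** Diets are applied either directly as uptake bounds
`(-flux, 0)` on diet-compartment exchanges, or through a food-item
constrained model in which each food gets an exchange reaction
(`foodItem[f] ←`, flux in g/day) and a breakdown reaction
(`foodItem[f] → Σ metᵢ[d] + Σ macro[d]`, coefficients per gram), with sink
reactions (`macro[d] →`) removing macronutrient pseudo-metabolites whose
flux then equals the macro content of the food actually eaten. A
feasibility check asks whether the maintenance objective can reach a
required value; if essential metabolites are missing, a greedy monotone
repair opens candidate uptakes until it can.

**Diet optimization.** A two-stage lexicographic LP: stage 1 maximizes the
weighted target fluxes over per-food addition/removal variables subject to
gram budgets, caloric-range and macro-tolerance constraints; stage 2 holds
the objective at a fraction *f* (default 0.999) of the stage-1 optimum and
minimizes total grams changed — the L1-minimal diet modification that still
delivers essentially the best achievable flux shift.

Everything runs on synthetic fixtures bundled with the package (a toy food
database embedding worked-example foods with planted properties, and a
deterministic toy whole-body-style model); no download is required.

## Worked example

```python
from dietforge import *
from dietforge.fixtures import FixtureSpec, make_toy_food_db, make_toy_wbm, \
    table2_equivalents_consumed
from dietforge import model_integration as mi, diet_optimization as do

db = make_toy_food_db(FixtureSpec(seed=1))
eq = table2_equivalents_consumed()      # date 50 g, apple 100 g, cheese 25 g
diet = build_diet(eq, db, "diet1")
```

The compiled diet (mmol/day/person) and its energy fractions:

```
fru        109.7104  mmol/day
glc_D       96.7612  mmol/day
leu_L        1.5000  mmol/day
lnlc         2.0000  mmol/day
thm          0.1000  mmol/day
trp_L        0.2500  mmol/day
{'carbohydrate': 0.673, 'protein': 0.039, 'lipid': 0.253, 'fibre': 0.036, 'alcohol': 0.0}
```

Applying the diet to the toy model and checking feasibility:

```python
model = make_toy_wbm()
constraints, skipped = mi.diet_to_constraints(diet, model)
mi.apply_diet(model, constraints)
mi.check_feasibility(model)             # feasible, objective 10.0
```

The maintenance objective reaches 10.0 (≥ the required 1.0), so this diet
sustains the model. Optimizing serotonin synthesis with at most 10 g of
food added, choosing from a tryptophan supplement:

```python
m2 = make_toy_wbm()
items = sorted(eq.consumption("diet1")) + [("usda", "900002")]
mi.add_food_reactions(m2, db, items)
spec = do.OptimizationSpec(targets=[("SRTN_SYN", "maximize", 1.0)],
                           level="food", max_added_g=10.0, max_removed_g=0.0,
                           candidate_foods=[("usda", "900002")])
plan = do.optimize_diet(m2, eq, spec, db, diet_name="diet1")
print(do.summarize_plan(plan, db))
```

```
Added:
  Supplement, tryptophan powder (usda 900002): 9.99 g/day (18.0 kcal)
Target objective: baseline 0.1250 -> achieved 10.1149 (stage-1 optimum 10.1250, f = 0.999)
Macronutrient totals (baseline -> new):
  carbohydrate_g: 52.50 -> 52.50 (delta +0.00)
  energy_kcal: 289.43 -> 307.42 (delta +17.98)
  ...
```

The baseline diet supports 0.125 mmol/day of serotonin synthesis (half the
0.25 mmol tryptophan uptake, since synthesis consumes 2 tryptophan per
unit). The full 10 g budget would raise it to 10.125; stage 2 keeps 99.9%
of that with 9.99 g — the smallest change that does.

A CLI mirrors the workflow (`dietforge fixtures`, `build-db`, `find-foods`,
`build-diet`, `apply-diet`, `optimize`); see `dietforge --help`.

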