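# Methods

This note documents the models, conventions and numerical choices behind
`dietforge`, in the order data flows through the package.

## Composition normalization (food_database)

A food-composition table is long-format: one row per (food, nutrient,
amount, unit), amounts per 100 g of food. Two schema descriptors ship:
`usda-fdc` (columns `fdc_id/description/nutrient_name/amount/unit_name`,
origin fixed to `usda`) and `generic` (an explicit `origin` column).

*Units.* Accepted mass units are g, mg, µg (also spelled `ug`); accepted
energy units are kcal and kJ (kJ/4.184 → kcal, the label convention).
Anything else is a per-row error collected in the load report, never a
silent drop — silent unit bugs are the classic failure mode of nutrition
data. Energy reported in a mass unit (or vice versa) is likewise an error.

*Mass → mmol.* `mmol/100 g = mass_g / MW × 1000`, exact arithmetic, no
rounding. Molecular weights and nutrient→metabolite mappings are plain
editable tables; a small default set (14 common metabolites in a VMH-style
namespace) is bundled. A metabolite without a molecular weight is excluded
from conversion with a warning rather than failing the load. Duplicate
(origin, id, nutrient) measurements keep the first value and warn.

*Macros vs metabolites.* Reported macronutrients (energy, lipid, protein,
total carbohydrate, sugars, fibre, starch, alcohol) and measured
metabolites are stored side by side and never mixed: metabolite-derived
macro summaries are always computed from the `metabolites` map alone
(`Σ mmol × MW / 1000` per group), so nothing is double-counted. Metabolites
without a group assignment count as `other`.

*Serialization.* One TSV holds the whole database: record rows
(`entry_type` ∈ {macro, metabolite}) plus metadata rows
(`molecular_weight`, `group`) so a single file round-trips without side
tables.

## Food matching (food_matching)

Keyword matching is case-insensitive substring search on record
descriptions, with punctuation collapsed to spaces and no stemming —
deterministic and language-agnostic. Two strategies:

- **cumulative** — a record matches iff every keyword occurs;
- **sequential** — keywords applied in order, each narrowing the survivor
  set; a keyword that would empty the set is skipped and logged. This
  encodes the guidance that the first keyword is the most descriptive: an
  over-specific trailing keyword cannot wipe out good hits.

Zero hits → the item goes to `noDatabaseHits.txt`. More than the cap
(default 50) → the raw hit list goes to `tooManyDatabaseHits.csv` for
keyword refinement. Hits in between are scored.

*Distance.* User macros are rescaled to per-100 g
(×100/reference weight) and compared by plain Euclidean distance over
exactly the fields the user supplied, drawn from {energy, lipid, protein,
sugars, fibre, starch}. Total carbohydrate is excluded by construction
(databases and labels disagree on whether fibre is included); the
unambiguous components are used instead. kcal and grams are mixed
unweighted; a per-field standardization switch was considered and left out
of the default because it changes rankings in ways users cannot easily
predict. A supplied field missing from a candidate counts as 0 and is
flagged per-field, keeping all candidates comparable.

*Coverage.* Per group with a reported macro > 0:
`100 × metabolite-derived mass / reported mass` (may exceed 100). The
carbohydrate reference is the reported total carbohydrate when present,
else the sum of reported sugars/fibre/starch; a group with no reported
macro is n/a, not 0. Ranking is (distance ↑, mean coverage ↓, food id ↑) —
a deterministic total order; items with no user macros rank by coverage.

The four report files are CSV (bit-exact, diffable); the short report holds
the top 10 candidates per item.

## Diet compilation (diet_builder)

`flux_m = Σ_foods mmol_m/100 g ÷ 100 × grams`, summed over rows —
linear in the gram column and additive over disjoint row sets; rows at
0 g contribute nothing. Macro summaries accumulate the same way, once from
database macros and once from metabolite-derived group masses.

Energy fractions use fixed, overridable energy densities: carbohydrate 4,
protein 4, lipid 9, fibre 2, alcohol 7 kcal/g (Atwater convention with the
common fibre/alcohol values). Fibre is kept as its own group rather than
folded into carbohydrate — whether reported totals include it varies by
source, and a separate group makes the choice visible instead of baked in.
An all-zero diet has undefined fractions (`None`), not zeros. Negative
consumed weights are rejected, not clamped.

## Model integration (model_integration)

COBRA sign convention throughout: negative exchange flux is uptake.

*Metabolite mode.* A diet becomes bounds `(-flux, -enforce_fraction ×
flux)` on `Diet_EX_<met>[d]` reactions; the default `enforce_fraction = 0`
allows uptake up to the dietary amount without forcing it. Applying a diet
first closes every diet exchange, then opens exactly the dietary ones —
otherwise metabolites the diet does not provide would leak in through
default-open exchanges and the feasibility check would be vacuous.
Metabolites with no exchange in the model are returned in a skip list,
never fatal. Stoichiometry is untouched.

*Food mode.* Per food item: an exchange `Food_EX_<origin>_<id>[f]` (flux
unit g/day, uptake-only) and a breakdown `Food_BD_<origin>_<id>` turning
1 g of the item into its metabolites in `[d]` (per-100 g values ÷ 100) and
its macronutrient pseudo-metabolites (`<macro>[d]`), each removed by a sink
`EX_<macro>[d]` added once per model. The pseudo-metabolites appear in no
other reaction (checked structurally in the tests), so their sinks cannot
alter any optimum — they are pure bookkeeping whose flux equals the macro
content of food actually broken down. A food metabolite foreign to the
model gets its `[d]` species created together with a free excretion route,
so one unknown compound cannot stall the breakdown of the whole item; the
creation is reported.

With free disposal routes the two modes are equivalent: any objective
optimum under metabolite bounds equals the optimum under the food-item
model with food exchanges fixed to the consumed grams (verified to 1e-6
over random diets in the tests).

*Feasibility.* `max c·v s.t. S·v = 0, lb ≤ v ≤ ub`; feasible means the LP
optimum reaches the required maintenance value (default 1, the usual
whole-body convention; configurable). Solver failure is distinct from
infeasibility. Repair is a greedy loop over an ordered candidate list of
(metabolite, increment) pairs: each trial widens the uptake lower bound by
the increment and re-solves, up to `max_rounds` passes, accumulating
increments — a pure relaxation, no uptake is ever reduced, and every
accepted change is logged and mirrored into the returned diet. The audit
trail of which increments were tried is the point; increment sizes and
ordering are configuration, with a documented toy default (thiamin 0.05,
then leucine 0.5 mmol/day).

## Diet optimization (diet_optimization)

Per candidate *i* (food item, or metabolite at metabolite level), variables
`add_i ≥ 0`, `rem_i ≤ current_i` perturb the baseline; the candidate's
exchange flux is **pinned** to `-(current_i + add_i - rem_i)`. Pinning —
rather than merely bounding — is deliberate: if uptake were optional, the
model could leave baseline food uneaten, making removal costless and macro
bands meaningless (baseline lipid could be silently swapped for candidate
lipid). With pinning, "the diet" is what is eaten; surplus leaves through
excretion routes. Consequence: the host model must be able to dispose of
every dietary metabolite, which whole-body-style models (and the toy model)
satisfy via fecal/excretion reactions.

Stage 1 maximizes `Σ weight × (±target flux)` subject to steady state, the
pins, budgets `Σ add ≤ max_added`, `Σ rem ≤ max_removed` (two separate
budgets; a shared budget is a one-line change in the constraint), a caloric
band on the energy sink flux, and per-group macro-tolerance bands centred
on the baseline's nominal macros. Stage 2 adds the guard
`objective ≥ opt₁ − (1 − f)·|opt₁|` and minimizes `Σ (add + rem)` in grams.
The guard is written sign-safely: a literal `f·opt₁` would be *stricter*
than the optimum whenever opt₁ < 0. `f` defaults to 0.999; backing off by
0.1% avoids the degenerate sensitivity of an exact equality to solver
tolerances while changing the answer by at most that fraction. Change
magnitude is L1 in grams — no integer variables, partial foods allowed; a
cardinality-constrained MILP mode is an extension hook, not implemented.

Metabolite-level budgets are expressed in grams through molecular weights
(`mmol × MW / 1000`), so a "200 g" budget means the same thing at both
levels; caloric and macro constraints then act on linear expressions of the
add/rem variables (group masses × Atwater factors) rather than sink fluxes.

The baseline objective is measured with add = rem = 0 *before* the caloric
and macro bands are installed — the status quo is the reference point, not
a plan that must satisfy the new constraints. If stage 1 is infeasible, the
constraint families (budgets, caloric range, macro tolerances) are relaxed
one at a time to name the binding group in the raised error.

Solver: GLPK through cobrapy/optlang. Reported changes below 1e-6
gram-equivalents are treated as zero; all other numbers are rounded only at
presentation.

## Synthetic fixtures (fixtures)

The toy database stands in for the processed output of the real USDA/FRIDA
pipelines at a few dozen foods over a 6-metabolite core pool (glucose,
fructose, leucine, tryptophan, linoleate, thiamin). It embeds the
documentation's worked-example foods under fixed identifiers (dried date
usda/168191, red apple usda/1105430, cream cheese frida/1215; the apple's
macros equal the documented per-150 g item rescaled to 100 g, so it matches
at distance 0) and two planted foods: a protein isolate whose leucine mass
is exactly 80% of its reported protein (known coverage), and a tryptophan
supplement at 2 mmol/g with a small unavoidable lipid load (the optimizer
oracle's candidate). Randomized foods draw 2–4 metabolites with
group-typical per-100 g amounts and report macros at 70–100% metabolite
coverage, so sub-100% coverage is always exercised; their word bank never
produces "apple", and `n_apple_hits` plants an exact number of
apple-containing descriptions for hit-cap tests. All draws come from one
seeded NumPy generator; same seed, byte-identical files.

The toy model is deterministic: diet `[d]` and cytosol `[c]` compartments,
diet exchanges, transports and free excretion per metabolite, ATP yields of
2/2/9 per glucose/fructose/linoleate, a maintenance objective consuming
10 ATP + 0.1 leucine + 0.01 thiamin per unit, and a serotonin target
consuming 2 tryptophan per unit — so the target's FBA maximum has the
closed form `tryptophan uptake / 2`, the independent oracle for optimizer
tests. The `missing_essential_metabolite` defect removes thiamin from every
food, making any diet built from the defective database infeasible until
repair re-adds it.

What the fixtures do *not* emulate: the scale (~14,000 USDA / ~1,400 FRIDA
foods) and nutrient breadth of real databases, measurement noise and
inter-database unit quirks beyond the handled set, organ-level resolution
and microbiome coupling of real whole-body models, and enzyme kinetics or
bioavailability (dietary uptake in any such model is an upper bound, not an
absorption model). Tests passing here show the algorithms are correct under
the stated conventions, not that a particular real diet-model pairing is
biologically calibrated.

## Problem sizes

Default test and acceptance runs use databases of 30–80 foods, a ~30
reaction toy model, 20 random diets for the equivalence check, 100 random
pairs for the unit-conversion check, and a 0.1 g brute-force grid over a
10 g budget — sizes at which every oracle is exactly computable while the
full suite runs in seconds.

## Known limitations

- Matching is literal substring search: no fuzzy matching, spelling
  correction or multilingual support.
- The Euclidean distance mixes kcal and grams unweighted; with several
  macros supplied, energy differences dominate numerically.
- The optimizer's pinned-consumption convention requires disposal routes in
  the host model (see above).
- Metabolite-level macro constraints use nominal Atwater arithmetic, not
  sink fluxes, and so ignore any model-internal fate of the metabolites.
- xlsx output is not produced; all reports are CSV/TSV/JSON.
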