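"""Minimal dietary changes that optimize target metabolic fluxes.

Given a model under a baseline diet, a set of target reactions (each to be
maximized or minimized), and budgets on how many grams of food may be added
or removed per day, the optimizer answers: *what is the smallest change to
the diet that achieves (almost) the best attainable shift in the targets?*

The formulation is a two-stage lexicographic linear program.  Per candidate
``i`` (a food item, or a metabolite when optimizing at metabolite level)
two variables ``add_i >= 0`` and ``rem_i >= 0`` perturb the baseline
consumption; the exchange flux of the candidate is pinned to the effective
consumption ``current_i + add_i - rem_i``, so macronutrient sink fluxes
track what is actually eaten and removal genuinely takes food off the
plate.  Stage 1 optimizes the weighted target objective subject to steady
state, the gram budgets, and any caloric-range or macro-tolerance
constraints.  Stage 2 freezes the stage-1 objective to a fraction ``f`` of
its optimum (default 0.999) and minimizes total change ``Σ (add_i +
rem_i)`` in grams — the L1-minimal diet modification that still delivers
essentially the best achievable flux shift.  Allowing the fraction to back
off by ``1 - f`` avoids the degenerate sensitivity of an exact equality to
solver tolerances, and is itself a tunable.

Metabolite-level changes are budgeted in grams through molecular weights
(``mmol × MW / 1000``), so a "200 g of food" idiom applies uniformly at
both levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from cobra import Model

from ._defaults import ATWATER_KCAL_PER_G
from .diet_builder import EquivalentsConsumed, InSilicoDiet
from .food_database import FoodDatabase
from .model_integration import (
    DIET_EXCHANGE_PREFIX,
    FOOD_EXCHANGE_PREFIX,
    SolverFailure,
    add_food_reactions,
    diet_exchange_id,
    food_exchange_id,
    macro_sink_id,
)

__all__ = [
    "OptimizationSpec",
    "DietChangePlan",
    "DietOptimizationInfeasible",
    "optimize_diet",
    "summarize_plan",
]

#: Macro-tolerance group -> macro sink key of the food-constrained model.
_GROUP_TO_MACRO_KEY = {
    "carbohydrate": "carbohydrate_g",
    "protein": "protein_g",
    "lipid": "lipid_g",
    "fibre": "fibre_g",
    "alcohol": "alcohol_g",
    "sugars": "sugars_g",
    "starch": "starch_g",
}

_CHANGE_EPS = 1e-6  # grams (or gram-equivalents) below this are reported as no change


class DietOptimizationInfeasible(RuntimeError):
    """No diet satisfies the constraint combination.

    ``binding_group`` names the constraint family whose removal restores
    feasibility (``"budgets"``, ``"caloric_range"``, ``"macro_tolerances"``)
    when one could be identified.
    """

    def __init__(self, message: str, binding_group: str | None = None):
        super().__init__(message)
        self.binding_group = binding_group


@dataclass
class OptimizationSpec:
    """What to optimize and how much the diet may change.

    ``targets`` are ``(reaction_id, direction, weight)`` triples with
    direction ``"maximize"`` or ``"minimize"`` and weight > 0.  Budgets are
    g/day; ``caloric_range`` bounds total dietary energy in kcal/day;
    ``macro_tolerances`` bounds the absolute change of each listed
    macronutrient group in g/day.  ``candidate_foods`` restricts which
    database items may be *added* (baseline foods can always be removed);
    at metabolite level ``candidate_metabolites`` plays the same role.
    """

    targets: list[tuple[str, str, float]]
    level: str = "food"  # "food" | "metabolite"
    max_added_g: float = 200.0
    max_removed_g: float = 200.0
    caloric_range: tuple[float, float] | None = None
    macro_tolerances: dict[str, float] | None = None
    candidate_foods: list[tuple[str, str]] | None = None
    candidate_metabolites: list[str] | None = None
    optimality_fraction: float = 0.999

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one optimization target is required")
        for rxn, direction, weight in self.targets:
            if direction not in ("maximize", "minimize"):
                raise ValueError(f"target {rxn!r}: direction must be maximize|minimize")
            if weight <= 0:
                raise ValueError(f"target {rxn!r}: weight must be > 0")
        if self.level not in ("food", "metabolite"):
            raise ValueError(f"level must be food|metabolite, got {self.level!r}")
        if self.max_added_g < 0 or self.max_removed_g < 0:
            raise ValueError("gram budgets must be >= 0")
        if self.caloric_range is not None and self.caloric_range[0] > self.caloric_range[1]:
            raise ValueError("caloric_range lower bound exceeds upper bound")
        if not 0.0 < self.optimality_fraction <= 1.0:
            raise ValueError("optimality_fraction must be in (0, 1]")
        if self.macro_tolerances:
            bad = set(self.macro_tolerances) - set(_GROUP_TO_MACRO_KEY)
            if bad:
                raise ValueError(f"unknown macro-tolerance groups {sorted(bad)}")


@dataclass
class DietChangePlan:
    """The optimizer's answer: what to add, what to remove, what it buys."""

    level: str
    added: dict = field(default_factory=dict)  # item or metabolite -> g/day (or mmol/day)
    removed: dict = field(default_factory=dict)
    baseline_target_flux: float = 0.0
    stage1_optimum: float = 0.0
    achieved_target_flux: float = 0.0
    optimality_fraction: float = 1.0
    target_fluxes: dict[str, float] = field(default_factory=dict)  # per target reaction
    new_macros: dict[str, float] = field(default_factory=dict)  # g/day; energy in kcal/day
    baseline_macros: dict[str, float] = field(default_factory=dict)

    @property
    def total_added(self) -> float:
        return sum(self.added.values())

    @property
    def total_removed(self) -> float:
        return sum(self.removed.values())


def _objective_threshold(optimum: float, fraction: float) -> float:
    # sign-safe "within fraction f of the optimum" for a maximization:
    # backing off by (1 - f)·|optimum| keeps the relaxation a relaxation
    # even when the optimum is negative
    return optimum - (1.0 - fraction) * abs(optimum)


class _StagedLP:
    """Shared scaffolding of the food- and metabolite-level programs."""

    def __init__(self, model: Model, spec: OptimizationSpec):
        self.model = model
        self.spec = spec
        self.prob = model.problem
        self.add_vars: dict = {}
        self.rem_vars: dict = {}
        self.grams_per_unit: dict = {}  # candidate -> grams per variable unit
        self.families: dict[str, list] = {"budgets": [], "caloric_range": [],
                                          "macro_tolerances": []}

    def new_pair(self, key, add_ub: float, rem_ub: float, grams_per_unit: float) -> None:
        tag = str(key).replace(" ", "_").replace("'", "").replace("(", "").replace(")", "")
        add = self.prob.Variable(f"df_add_{tag}", lb=0.0, ub=max(add_ub, 0.0))
        rem = self.prob.Variable(f"df_rem_{tag}", lb=0.0, ub=max(rem_ub, 0.0))
        self.model.add_cons_vars([add, rem])
        self.add_vars[key] = add
        self.rem_vars[key] = rem
        self.grams_per_unit[key] = grams_per_unit

    def pin_exchange(self, key, rxn_id: str, current: float) -> None:
        """Fix exchange flux to -(current + add - rem)."""
        rxn = self.model.reactions.get_by_id(rxn_id)
        big = 1e7
        rxn.bounds = (-big, big)
        c = self.prob.Constraint(
            rxn.flux_expression + self.add_vars[key] - self.rem_vars[key],
            lb=-current, ub=-current, name=f"df_pin_{rxn_id}")
        self.model.add_cons_vars([c])

    def add_budgets(self) -> None:
        add_expr = sum(self.grams_per_unit[k] * v for k, v in self.add_vars.items())
        rem_expr = sum(self.grams_per_unit[k] * v for k, v in self.rem_vars.items())
        ca = self.prob.Constraint(add_expr, ub=self.spec.max_added_g, name="df_budget_add")
        cr = self.prob.Constraint(rem_expr, ub=self.spec.max_removed_g, name="df_budget_rem")
        self.model.add_cons_vars([ca, cr])
        self.families["budgets"] += [ca, cr]

    def band_constraint(self, expr, lb: float, ub: float, name: str, family: str) -> None:
        c = self.prob.Constraint(expr, lb=lb, ub=ub, name=name)
        self.model.add_cons_vars([c])
        self.families[family].append(c)

    # -------------------------------------------------------------- solve

    def _solve(self) -> float | None:
        self.model.solver.optimize()
        status = self.model.solver.status
        if status == "optimal":
            return self.model.solver.objective.value
        if status in ("infeasible", "undefined"):
            return None
        if status == "unbounded":
            raise SolverFailure("target objective is unbounded; add budgets or bounds")
        raise SolverFailure(f"solver returned status {status!r}")

    def _diagnose(self) -> str | None:
        for name, cons in self.families.items():
            if not cons:
                continue
            saved = [(c, c.lb, c.ub) for c in cons]
            for c, _, _ in saved:
                c.lb, c.ub = None, None
            feasible = self._solve() is not None
            for c, lb, ub in saved:
                c.lb, c.ub = lb, ub
            if feasible:
                return name
        return None

    def run_stages(self, objective_expr) -> tuple[float, float, dict]:
        """Stage 1 then stage 2; returns (opt1, achieved objective, primal values)."""
        spec = self.spec
        self.model.objective = self.prob.Objective(objective_expr, direction="max")
        opt1 = self._solve()
        if opt1 is None:
            group = self._diagnose()
            raise DietOptimizationInfeasible(
                "no diet satisfies the constraints"
                + (f" (binding constraint group: {group})" if group else ""),
                binding_group=group)

        guard = self.prob.Constraint(objective_expr,
                                     lb=_objective_threshold(opt1, spec.optimality_fraction),
                                     name="df_stage1_guard")
        self.model.add_cons_vars([guard])
        change = sum(self.grams_per_unit[k] * v for k, v in self.add_vars.items()) \
            + sum(self.grams_per_unit[k] * v for k, v in self.rem_vars.items())
        self.model.objective = self.prob.Objective(change, direction="min")
        if self._solve() is None:  # numerically possible only at the guard boundary
            guard.lb = guard.lb - 1e-9 * max(1.0, abs(opt1))
            if self._solve() is None:
                raise SolverFailure("stage 2 infeasible despite stage-1 optimum")
        primals = {"add": {k: max(0.0, v.primal) for k, v in self.add_vars.items()},
                   "rem": {k: max(0.0, v.primal) for k, v in self.rem_vars.items()}}
        achieved = self._expr_value(objective_expr)
        return opt1, achieved, primals

    def _expr_value(self, expr) -> float:
        # evaluate a linear sympy expression at the current primal point
        total = 0.0
        for var, coef in expr.as_coefficients_dict().items():
            if var == 1:
                total += float(coef)
            else:
                total += float(coef) * float(var.primal)
        return total


def _target_expression(model: Model, targets: Sequence[tuple[str, str, float]]):
    expr = 0
    for rxn_id, direction, weight in targets:
        if rxn_id not in model.reactions:
            raise KeyError(f"target reaction {rxn_id!r} not in model")
        sign = 1.0 if direction == "maximize" else -1.0
        expr = expr + sign * weight * model.reactions.get_by_id(rxn_id).flux_expression
    return expr


def _baseline_objective(model: Model, spec: OptimizationSpec) -> tuple[float, dict[str, float]]:
    """Stage-1 objective value and per-target fluxes with the diet unchanged."""
    with model:
        expr = _target_expression(model, spec.targets)
        model.objective = model.problem.Objective(expr, direction="max")
        model.solver.optimize()
        if model.solver.status != "optimal":
            raise DietOptimizationInfeasible(
                f"model infeasible under the baseline diet (status {model.solver.status})")
        value = model.solver.objective.value
        fluxes = {rxn_id: model.reactions.get_by_id(rxn_id).flux
                  for rxn_id, _, _ in spec.targets}
    return value, fluxes


def _nominal_food_macros(db: FoodDatabase,
                         consumption: Mapping[tuple[str, str], float]) -> dict[str, float]:
    out: dict[str, float] = {}
    for (origin, fid), grams in consumption.items():
        rec = db.get(origin, fid)
        for key, val in rec.macronutrients.items():
            out[key] = out.get(key, 0.0) + val * grams / 100.0
    return out


def _metabolite_masses(db: FoodDatabase, flux: Mapping[str, float]) -> dict[str, float]:
    """Group masses (g/day) plus Atwater energy implied by a metabolite flux vector."""
    out = {"carbohydrate": 0.0, "protein": 0.0, "lipid": 0.0, "other": 0.0}
    for met, mmol in flux.items():
        mw = db.molecular_weights[met]
        out[db.group_of(met)] += mmol * mw / 1000.0
    out["energy_kcal"] = sum(out[g] * f for g, f in ATWATER_KCAL_PER_G.items() if g in out)
    return out


def optimize_diet(
    model: Model,
    baseline: EquivalentsConsumed | InSilicoDiet,
    spec: OptimizationSpec,
    db: FoodDatabase,
    diet_name: str | None = None,
) -> DietChangePlan:
    """Compute the minimal dietary change that best shifts the target fluxes.

    Parameters
    ----------
    model
        For ``spec.level == "food"``: a food-item-constrained model (food
        exchange + breakdown reactions present; any candidate foods still
        missing are added here).  For ``"metabolite"``: a model with diet
        exchange reactions.  The model is copied; the input is untouched.
    baseline
        The current diet — an :class:`EquivalentsConsumed` (food level,
        with ``diet_name`` selecting the gram column) or an
        :class:`InSilicoDiet` (metabolite level).
    spec
        Targets, budgets and constraints.
    db
        Food database supplying composition, molecular weights and groups.

    Returns
    -------
    DietChangePlan
        Stage-2 solution: additions/removals above 1e-6 g(-equivalent),
        baseline and achieved objective values, per-target fluxes, and the
        macronutrient totals of the modified diet.
    """
    if spec.level == "food":
        return _optimize_food_level(model, baseline, spec, db, diet_name)
    return _optimize_metabolite_level(model, baseline, spec, db)


def _optimize_food_level(model, consumed, spec, db, diet_name):
    if not isinstance(consumed, EquivalentsConsumed):
        raise TypeError("food-level optimization expects an EquivalentsConsumed baseline")
    if diet_name is None:
        diet_name = consumed.diet_names[0]
    current = consumed.consumption(diet_name)
    candidates: dict[tuple[str, str], float] = dict(current)
    for item in spec.candidate_foods or []:
        candidates.setdefault((str(item[0]), str(item[1])), 0.0)

    work = model.copy()
    missing = [item for item in candidates
               if food_exchange_id(*item) not in work.reactions]
    if missing:
        add_food_reactions(work, db, missing)

    # only the candidate foods are edible; diet exchanges stay shut so the
    # food route is the sole dietary input
    for rxn in work.reactions:
        if rxn.id.startswith((FOOD_EXCHANGE_PREFIX, DIET_EXCHANGE_PREFIX)):
            rxn.bounds = (0.0, 0.0)

    lp = _StagedLP(work, spec)
    allowed_adds = (None if spec.candidate_foods is None
                    else {(str(o), str(i)) for o, i in spec.candidate_foods})
    for item, cur in candidates.items():
        add_ub = spec.max_added_g if (allowed_adds is None or item in allowed_adds) else 0.0
        lp.new_pair(item, add_ub=add_ub, rem_ub=min(cur, spec.max_removed_g),
                    grams_per_unit=1.0)
        lp.pin_exchange(item, food_exchange_id(*item), cur)
    lp.add_budgets()

    # baseline objective with add = rem = 0, measured before the caloric and
    # macro bands exist: the status quo is the reference, not a plan
    clamps = [(v, v.ub) for v in list(lp.add_vars.values()) + list(lp.rem_vars.values())]
    for v, _ in clamps:
        v.ub = 0.0
    expr = _target_expression(work, spec.targets)
    work.objective = work.problem.Objective(expr, direction="max")
    work.solver.optimize()
    if work.solver.status != "optimal":
        raise DietOptimizationInfeasible(
            f"model infeasible under the baseline diet (status {work.solver.status})")
    baseline_obj = work.solver.objective.value
    for v, ub in clamps:
        v.ub = ub

    baseline_macros = _nominal_food_macros(db, current)
    if spec.caloric_range is not None:
        sink = macro_sink_id("energy_kcal")
        if sink not in work.reactions:
            raise KeyError("model lacks the energy sink reaction needed for a caloric range")
        lp.band_constraint(work.reactions.get_by_id(sink).flux_expression,
                           spec.caloric_range[0], spec.caloric_range[1],
                           "df_caloric_range", "caloric_range")
    for group, tol in (spec.macro_tolerances or {}).items():
        sink = macro_sink_id(_GROUP_TO_MACRO_KEY[group])
        if sink not in work.reactions:
            raise KeyError(f"model lacks the {group} macro sink needed for its tolerance")
        base = baseline_macros.get(_GROUP_TO_MACRO_KEY[group], 0.0)
        lp.band_constraint(work.reactions.get_by_id(sink).flux_expression,
                           max(0.0, base - tol), base + tol,
                           f"df_macro_tol_{group}", "macro_tolerances")

    opt1, achieved, primals = lp.run_stages(expr)
    plan = DietChangePlan(
        level="food",
        added={k: v for k, v in primals["add"].items() if v > _CHANGE_EPS},
        removed={k: v for k, v in primals["rem"].items() if v > _CHANGE_EPS},
        baseline_target_flux=baseline_obj,
        stage1_optimum=opt1,
        achieved_target_flux=achieved,
        optimality_fraction=spec.optimality_fraction,
        target_fluxes={rxn_id: work.reactions.get_by_id(rxn_id).flux
                       for rxn_id, _, _ in spec.targets},
        baseline_macros=baseline_macros,
    )
    new_consumption = {
        item: cur + primals["add"].get(item, 0.0) - primals["rem"].get(item, 0.0)
        for item, cur in candidates.items()}
    plan.new_macros = _nominal_food_macros(db, new_consumption)
    return plan


def _optimize_metabolite_level(model, diet, spec, db):
    if not isinstance(diet, InSilicoDiet):
        raise TypeError("metabolite-level optimization expects an InSilicoDiet baseline")
    current: dict[str, float] = dict(diet.flux)
    candidates = dict(current)
    for met in spec.candidate_metabolites or []:
        candidates.setdefault(met, 0.0)

    work = model.copy()
    usable = {}
    for met, cur in candidates.items():
        rxn_id = diet_exchange_id(met)
        if rxn_id not in work.reactions:
            if cur > 0:
                raise KeyError(f"model lacks diet exchange for baseline metabolite {met!r}")
            continue  # candidate metabolite unknown to the model: cannot help
        if met not in db.molecular_weights:
            raise KeyError(f"metabolite {met!r} lacks a molecular weight")
        usable[met] = cur
    for rxn in work.reactions:
        if rxn.id.startswith(DIET_EXCHANGE_PREFIX):
            rxn.bounds = (0.0, 0.0)

    lp = _StagedLP(work, spec)
    for met, cur in usable.items():
        g_per_mmol = db.molecular_weights[met] / 1000.0
        addable = spec.candidate_metabolites is None or met in spec.candidate_metabolites
        add_cap = (spec.max_added_g / g_per_mmol) if addable else 0.0
        lp.new_pair(met, add_ub=add_cap, rem_ub=cur, grams_per_unit=g_per_mmol)
        lp.pin_exchange(met, diet_exchange_id(met), cur)
    lp.add_budgets()

    clamps = [(v, v.ub) for v in list(lp.add_vars.values()) + list(lp.rem_vars.values())]
    for v, _ in clamps:
        v.ub = 0.0
    expr = _target_expression(work, spec.targets)
    work.objective = work.problem.Objective(expr, direction="max")
    work.solver.optimize()
    if work.solver.status != "optimal":
        raise DietOptimizationInfeasible(
            f"model infeasible under the baseline diet (status {work.solver.status})")
    baseline_obj = work.solver.objective.value
    for v, ub in clamps:
        v.ub = ub

    baseline_masses = _metabolite_masses(db, usable)
    uptake_mass_exprs: dict[str, object] = {}
    for met in usable:
        g_per_mmol = db.molecular_weights[met] / 1000.0
        group = db.group_of(met)
        mass_expr = g_per_mmol * (lp.add_vars[met] - lp.rem_vars[met])
        uptake_mass_exprs[group] = uptake_mass_exprs.get(group, 0) + mass_expr
    if spec.caloric_range is not None:
        energy_change = sum(ATWATER_KCAL_PER_G.get(g, 0.0) * e
                            for g, e in uptake_mass_exprs.items())
        base = baseline_masses["energy_kcal"]
        lp.band_constraint(energy_change, spec.caloric_range[0] - base,
                           spec.caloric_range[1] - base, "df_caloric_range", "caloric_range")
    for group, tol in (spec.macro_tolerances or {}).items():
        band_expr = uptake_mass_exprs.get(group)
        if band_expr is None:
            continue  # no candidate carries this group: change is identically 0
        lp.band_constraint(band_expr, -tol, tol, f"df_macro_tol_{group}", "macro_tolerances")

    opt1, achieved, primals = lp.run_stages(expr)
    plan = DietChangePlan(
        level="metabolite",
        added={k: v for k, v in primals["add"].items()
               if v * lp.grams_per_unit[k] > _CHANGE_EPS},
        removed={k: v for k, v in primals["rem"].items()
                 if v * lp.grams_per_unit[k] > _CHANGE_EPS},
        baseline_target_flux=baseline_obj,
        stage1_optimum=opt1,
        achieved_target_flux=achieved,
        optimality_fraction=spec.optimality_fraction,
        target_fluxes={rxn_id: work.reactions.get_by_id(rxn_id).flux
                       for rxn_id, _, _ in spec.targets},
        baseline_macros=baseline_masses,
    )
    new_flux = {met: cur + primals["add"].get(met, 0.0) - primals["rem"].get(met, 0.0)
                for met, cur in usable.items()}
    plan.new_macros = _metabolite_masses(db, new_flux)
    return plan


def summarize_plan(plan: DietChangePlan, db: FoodDatabase) -> str:
    """Human-readable account of a diet change plan."""
    lines: list[str] = []
    if not plan.added and not plan.removed:
        lines.append("No dietary change required.")
    else:
        if plan.added:
            lines.append("Added:")
            for key, amount in sorted(plan.added.items(), key=lambda kv: -kv[1]):
                lines.append("  " + _describe_change(plan.level, key, amount, db))
        if plan.removed:
            lines.append("Removed:")
            for key, amount in sorted(plan.removed.items(), key=lambda kv: -kv[1]):
                lines.append("  " + _describe_change(plan.level, key, amount, db))
    lines.append(f"Target objective: baseline {plan.baseline_target_flux:.4f} -> "
                 f"achieved {plan.achieved_target_flux:.4f} "
                 f"(stage-1 optimum {plan.stage1_optimum:.4f}, "
                 f"f = {plan.optimality_fraction})")
    keys = sorted(set(plan.baseline_macros) | set(plan.new_macros))
    if keys:
        lines.append("Macronutrient totals (baseline -> new):")
        for k in keys:
            b = plan.baseline_macros.get(k, 0.0)
            n = plan.new_macros.get(k, 0.0)
            lines.append(f"  {k}: {b:.2f} -> {n:.2f} (delta {n - b:+.2f})")
    return "\n".join(lines)


def _describe_change(level: str, key, amount: float, db: FoodDatabase) -> str:
    if level == "food":
        origin, fid = key
        desc = db.records.get((origin, fid))
        name = desc.description if desc else f"{origin}:{fid}"
        kcal = (desc.macronutrients.get("energy_kcal", 0.0) * amount / 100.0) if desc else 0.0
        return f"{name} ({origin} {fid}): {amount:.2f} g/day ({kcal:.1f} kcal)"
    grams = amount * db.molecular_weights.get(key, 0.0) / 1000.0
    return f"{key}: {amount:.3f} mmol/day ({grams:.3f} g/day)"
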