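"""Apply *in silico* diets to constraint-based models.

Two application modes exist.  *Metabolite mode* writes the diet straight
onto the diet-compartment exchange reactions: a metabolite available at
``x`` mmol/day gets uptake bounds ``(-x, 0)`` (COBRA convention: negative
exchange flux is uptake).  *Food mode* first augments the model so that it
can "eat" intact food items: per food equivalent an exchange reaction
imports the item into a food compartment ``[f]`` (flux unit g/day), and a
breakdown reaction converts 1 g of it into its constituent metabolites in
the diet compartment ``[d]`` plus macronutrient pseudo-metabolites (energy,
lipid, protein, ...).  The pseudo-metabolites never touch the metabolic
network; each is removed by a sink reaction whose flux therefore equals the
macro content of the food actually eaten — which is what lets a diet
optimizer put caloric and macronutrient constraints directly on the model.

Feasibility of a whole-body-style model is its ability to drive the
maintenance objective to a required value.  When a diet misses an essential
metabolite, :func:`restore_feasibility` relaxes uptake over a candidate
list, greedily and monotonically, until the objective is satisfiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
from cobra import Metabolite, Model, Reaction

from .diet_builder import InSilicoDiet
from .food_database import FoodDatabase, FoodRecord

__all__ = [
    "DIET_EXCHANGE_PREFIX",
    "FOOD_EXCHANGE_PREFIX",
    "FOOD_BREAKDOWN_PREFIX",
    "SolverFailure",
    "FeasibilityResult",
    "FoodReactionReport",
    "diet_exchange_id",
    "food_exchange_id",
    "diet_to_constraints",
    "add_food_reactions",
    "apply_diet",
    "apply_food_diet",
    "check_feasibility",
    "restore_feasibility",
    "maximize_reaction",
]

DIET_EXCHANGE_PREFIX = "Diet_EX_"
FOOD_EXCHANGE_PREFIX = "Food_EX_"
FOOD_BREAKDOWN_PREFIX = "Food_BD_"
_UPTAKE_BIG = 1e6  # effectively unbounded food import before diet bounds apply


class SolverFailure(RuntimeError):
    """The LP solver returned neither an optimum nor a clean infeasibility."""


@dataclass
class FeasibilityResult:
    """Outcome of a feasibility check or repair."""

    status: str  # "feasible" | "infeasible"
    objective_value: float | None = None
    adjustments: list[tuple[str, float]] = field(default_factory=list)  # (metabolite, mmol/day added)

    @property
    def feasible(self) -> bool:
        return self.status == "feasible"


def diet_exchange_id(metabolite_id: str, naming: str = DIET_EXCHANGE_PREFIX + "{met}[d]") -> str:
    return naming.format(met=metabolite_id)


def food_exchange_id(origin: str, food_id: str) -> str:
    return f"{FOOD_EXCHANGE_PREFIX}{origin}_{food_id}[f]"


def food_breakdown_id(origin: str, food_id: str) -> str:
    return f"{FOOD_BREAKDOWN_PREFIX}{origin}_{food_id}"


def macro_sink_id(macro_key: str) -> str:
    return f"EX_{macro_key}[d]"


def diet_to_constraints(
    diet: InSilicoDiet,
    model: Model | None = None,
    naming: str = DIET_EXCHANGE_PREFIX + "{met}[d]",
    enforce_fraction: float = 0.0,
) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Translate a diet flux vector into diet-exchange bounds.

    A metabolite available at ``x`` mmol/day becomes bounds
    ``(-x, -enforce_fraction * x)`` on its diet exchange: uptake up to the
    dietary amount, optionally forced (``enforce_fraction=1`` pins uptake to
    the full amount).  When a model is given, metabolites whose exchange
    reaction it lacks are diverted to the returned skip list instead of the
    constraint set.
    """
    if not 0.0 <= enforce_fraction <= 1.0:
        raise ValueError(f"enforce_fraction must be in [0, 1], got {enforce_fraction}")
    constraints: dict[str, tuple[float, float]] = {}
    skipped: list[str] = []
    known = {r.id for r in model.reactions} if model is not None else None
    for met, flux in sorted(diet.flux.items()):
        if flux < 0:
            raise ValueError(f"diet flux for {met!r} is negative ({flux})")
        rxn_id = diet_exchange_id(met, naming)
        if known is not None and rxn_id not in known:
            skipped.append(met)
            continue
        constraints[rxn_id] = (-flux, -enforce_fraction * flux)
    return constraints, skipped


@dataclass
class FoodReactionReport:
    """What :func:`add_food_reactions` created."""

    food_exchanges: list[str] = field(default_factory=list)
    breakdown_reactions: list[str] = field(default_factory=list)
    macro_sinks: list[str] = field(default_factory=list)
    created_diet_metabolites: list[str] = field(default_factory=list)


def _ensure_diet_species(model: Model, met_id: str, report: FoodReactionReport) -> Metabolite:
    """Fetch or create a diet-compartment species, with a free excretion route.

    A breakdown reaction runs only if every product can be consumed or
    disposed of; a metabolite foreign to the model therefore gets a sink so
    it cannot stall the breakdown of the whole food item.
    """
    full = f"{met_id}[d]"
    if full in model.metabolites:
        return model.metabolites.get_by_id(full)
    met = Metabolite(full, name=met_id, compartment="d")
    sink = Reaction(f"EX_{met_id}[d]_excretion", lower_bound=0.0, upper_bound=_UPTAKE_BIG)
    sink.add_metabolites({met: -1.0})
    model.add_reactions([sink])
    report.created_diet_metabolites.append(full)
    return met


def add_food_reactions(
    model: Model,
    db: FoodDatabase,
    items: Sequence[tuple[str, str]],
) -> FoodReactionReport:
    """Augment a model with food exchange and breakdown reactions.

    Per item ``(origin, food_id)``:

    * ``Food_EX_<origin>_<id>[f]`` — boundary exchange of the intact food
      item in the food compartment; negative flux is consumption, in g/day.
    * ``Food_BD_<origin>_<id>`` — breakdown of 1 g of the item into its
      measured metabolites in ``[d]`` (coefficient = mmol/100 g ÷ 100) and
      its macronutrient pseudo-metabolites (coefficient = macro/100 g ÷ 100).

    One sink per macronutrient pseudo-metabolite (``EX_<macro>[d]``) is
    added the first time it is needed; its flux equals the macro mass (or
    kcal) of food actually broken down.  The model is modified in place.
    """
    report = FoodReactionReport()
    for origin, food_id in items:
        rec = db.get(origin, food_id)
        ex_id = food_exchange_id(origin, food_id)
        if ex_id in model.reactions:
            raise ValueError(f"food reactions for ({origin}, {food_id}) already present")

        food_met = Metabolite(f"food_{origin}_{food_id}[f]", name=rec.description,
                              compartment="f")
        exchange = Reaction(ex_id, lower_bound=-_UPTAKE_BIG, upper_bound=0.0)
        exchange.add_metabolites({food_met: -1.0})

        breakdown = Reaction(food_breakdown_id(origin, food_id),
                             lower_bound=0.0, upper_bound=_UPTAKE_BIG)
        stoich: dict[Metabolite, float] = {food_met: -1.0}
        model.add_reactions([exchange])  # registers food_met so lookups below see it
        for met_id, mmol_per_100g in sorted(rec.metabolites.items()):
            met = _ensure_diet_species(model, met_id, report)
            stoich[met] = stoich.get(met, 0.0) + mmol_per_100g / 100.0
        for macro_key, per_100g in sorted(rec.macronutrients.items()):
            macro_full = f"{macro_key}[d]"
            if macro_full in model.metabolites:
                macro_met = model.metabolites.get_by_id(macro_full)
            else:
                macro_met = Metabolite(macro_full, name=macro_key, compartment="d")
                sink = Reaction(macro_sink_id(macro_key), lower_bound=0.0,
                                upper_bound=_UPTAKE_BIG)
                sink.add_metabolites({macro_met: -1.0})
                model.add_reactions([sink])
                report.macro_sinks.append(sink.id)
            stoich[macro_met] = stoich.get(macro_met, 0.0) + per_100g / 100.0
        breakdown.add_metabolites(stoich)
        model.add_reactions([breakdown])
        report.food_exchanges.append(ex_id)
        report.breakdown_reactions.append(breakdown.id)
    return report


def apply_diet(
    model: Model,
    constraints: Mapping[str, tuple[float, float]],
    close_prefix: str | None = DIET_EXCHANGE_PREFIX,
) -> Model:
    """Overwrite exchange bounds with a diet constraint set (in place).

    With ``close_prefix`` (default: the diet-exchange prefix) every reaction
    carrying that prefix is first closed to ``(0, 0)``, so metabolites the
    diet does not provide cannot leak in; the constraint set then reopens
    exactly the dietary ones.  Pass ``close_prefix=None`` to touch only the
    listed reactions.  Unknown reaction ids raise.
    """
    unknown = [r for r in constraints if r not in model.reactions]
    if unknown:
        raise KeyError(f"reactions not in model: {unknown}")
    if close_prefix is not None:
        for rxn in model.reactions:
            if rxn.id.startswith(close_prefix):
                rxn.bounds = (0.0, 0.0)
    for rxn_id, (lb, ub) in constraints.items():
        if lb > ub:
            raise ValueError(f"{rxn_id}: lower bound {lb} > upper bound {ub}")
        model.reactions.get_by_id(rxn_id).bounds = (lb, ub)
    return model


def apply_food_diet(
    model: Model,
    consumption: Mapping[tuple[str, str], float],
    enforce_fraction: float = 0.0,
    close_diet_exchanges: bool = True,
) -> Model:
    """Constrain food exchanges to consumed grams (food mode, in place).

    Each consumed item gets bounds ``(-grams, -enforce_fraction * grams)``
    on its food exchange; unconsumed food exchanges are closed.  By default
    the plain diet exchanges are closed too, so the food route is the sole
    dietary input.
    """
    if not 0.0 <= enforce_fraction <= 1.0:
        raise ValueError(f"enforce_fraction must be in [0, 1], got {enforce_fraction}")
    wanted = {food_exchange_id(o, i): g for (o, i), g in consumption.items()}
    unknown = [r for r in wanted if r not in model.reactions]
    if unknown:
        raise KeyError(f"food exchanges not in model: {unknown}")
    for rxn in model.reactions:
        if rxn.id.startswith(FOOD_EXCHANGE_PREFIX):
            rxn.bounds = (0.0, 0.0)
        elif close_diet_exchanges and rxn.id.startswith(DIET_EXCHANGE_PREFIX):
            rxn.bounds = (0.0, 0.0)
    for rxn_id, grams in wanted.items():
        if grams < 0:
            raise ValueError(f"{rxn_id}: negative consumption {grams}")
        model.reactions.get_by_id(rxn_id).bounds = (-grams, -enforce_fraction * grams)
    return model


def _optimize(model: Model) -> float | None:
    """Optimize the model objective.

    Returns the optimum, ``None`` for a cleanly infeasible LP, ``inf`` (or
    ``-inf`` when minimizing) for an unbounded one, and raises
    :class:`SolverFailure` for anything else.
    """
    model.solver.optimize()
    status = model.solver.status
    if status == "optimal":
        return model.solver.objective.value
    if status in ("infeasible", "undefined"):
        return None
    if status == "unbounded":
        return float("inf") if model.objective_direction == "max" else float("-inf")
    raise SolverFailure(f"solver returned status {status!r}")


def check_feasibility(model: Model, required_objective: float = 1.0) -> FeasibilityResult:
    """Can the model drive its (maintenance) objective to the required value?

    Solves ``max c·v  s.t.  S·v = 0, lb <= v <= ub``.  Feasible means the LP
    has an optimum and that optimum reaches ``required_objective``.
    """
    if len(cobra.util.solver.linear_reaction_coefficients(model)) == 0:
        raise ValueError("model has no objective reaction set")
    model.objective_direction = "max"
    optimum = _optimize(model)
    if optimum is None or optimum < required_objective - 1e-9:
        return FeasibilityResult(status="infeasible",
                                 objective_value=optimum)
    return FeasibilityResult(status="feasible", objective_value=optimum)


def restore_feasibility(
    model: Model,
    diet: InSilicoDiet,
    essential_candidates: Sequence[tuple[str, float]],
    required_objective: float = 1.0,
    max_rounds: int = 3,
    naming: str = DIET_EXCHANGE_PREFIX + "{met}[d]",
) -> tuple[FeasibilityResult, InSilicoDiet]:
    """Greedily open uptake of candidate metabolites until the model is feasible.

    Candidates ``(metabolite_id, increment mmol/day)`` are tried in order;
    each trial widens the uptake lower bound of the metabolite's diet
    exchange by the increment (a pure relaxation — no uptake is ever
    reduced) and re-solves.  Up to ``max_rounds`` passes over the list are
    made, so a model missing several essentials accumulates increments.
    Every accepted change is recorded and mirrored into the returned
    adjusted diet.  If the list is exhausted the result is infeasible with
    the full adjustment log.
    """
    adjusted = diet.copy()
    result = check_feasibility(model, required_objective)
    if result.feasible:
        return result, adjusted

    adjustments: list[tuple[str, float]] = []
    for _ in range(max_rounds):
        for met, increment in essential_candidates:
            if increment <= 0:
                raise ValueError(f"candidate increment for {met!r} must be > 0")
            rxn_id = diet_exchange_id(met, naming)
            if rxn_id not in model.reactions:
                continue
            rxn = model.reactions.get_by_id(rxn_id)
            lb, ub = rxn.bounds
            rxn.bounds = (lb - increment, min(ub, 0.0))
            adjustments.append((met, increment))
            adjusted.flux[met] = adjusted.flux.get(met, 0.0) + increment
            result = check_feasibility(model, required_objective)
            if result.feasible:
                result.adjustments = adjustments
                return result, adjusted
    result = check_feasibility(model, required_objective)
    result.adjustments = adjustments
    return result, adjusted


def maximize_reaction(model: Model, reaction_id: str, direction: str = "max") -> float | None:
    """FBA optimum of one reaction's flux; None if infeasible."""
    if reaction_id not in model.reactions:
        raise KeyError(f"reaction {reaction_id!r} not in model")
    with model:
        model.objective = model.reactions.get_by_id(reaction_id)
        model.objective_direction = direction
        return _optimize(model)
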