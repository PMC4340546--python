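"""Flux-variability analysis and capacity analyses over a context model.

All functions here operate on the *locked* feasible space of a
:class:`~contextflux.context.ContextModel` (or, via
``ContextModel.from_network``, on a plain steady-state space): per-reaction
flux ranges, per-metabolite production capacity summed over compartments,
NADH/NADPH redox capacity, pathway median fold-changes, single-knockout
essentiality and the forced-activity coupling scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .context import ContextModel
from .lp import INFEASIBLE, OPTIMAL, UNBOUNDED, InfeasibleError, LinearModel
from .network import Reaction
from .stats import wilcoxon_ranksum

#: floor applied to fold-change denominators; capacities below it count as zero
CAPACITY_FLOOR = 1e-9
#: solver round-off allowed when comparing range endpoints
SOLVER_TOL = 1e-6


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float
    status: str = OPTIMAL  # "optimal" or a per-reaction failure label


@dataclass
class CapacityTable:
    """Max production rate per species, summed over its compartments."""

    capacities: dict[str, float]
    per_compartment: dict[tuple[str, str], float] = field(default_factory=dict)
    infeasible: set[str] = field(default_factory=set)


@dataclass
class CouplingScanResult:
    per_reaction: dict[str, float]
    infeasible: set[str]
    reference_reaction: str | None
    reference_capacity: float
    comparison: dict | None = None


def run_fva(
    model: ContextModel, reactions: list[str] | None = None
) -> list[FluxRange]:
    """Min and max attainable flux per reaction over the locked space.

    Two optimisations per reaction; a per-reaction solver failure yields a
    flagged range and the scan continues.  Results are independent of the
    order reactions are scanned in (each solve is stateless).
    """
    if reactions is None:
        reactions = [r.id for r in model.network.reactions]
    out: list[FluxRange] = []
    for rxn_id in reactions:
        prob = model.build_problem()
        v = f"v_{rxn_id}"
        lo_sol = prob.solve({v: 1.0}, "min")
        hi_sol = prob.solve({v: 1.0}, "max")
        if lo_sol.status == INFEASIBLE or hi_sol.status == INFEASIBLE:
            raise InfeasibleError(
                f"context model infeasible while scanning {rxn_id!r}"
            )
        if not (lo_sol.ok and hi_sol.ok):
            out.append(FluxRange(rxn_id, math.nan, math.nan, UNBOUNDED))
            continue
        lo, hi = lo_sol.objective, hi_sol.objective
        if lo > hi:  # solver round-off on a point range
            lo = hi = 0.5 * (lo + hi)
        out.append(FluxRange(rxn_id, lo, hi))
    return out


#: redox cofactors whose "production" means regeneration from the oxidised form
COFACTOR_PAIRS = {"nadh": "nad", "nadph": "nadp"}


def _drain_reactions(model: ContextModel, species_key: str) -> list[Reaction]:
    """Transient drains measuring production of a species.

    For a redox cofactor (NADH, NADPH) the drain converts the reduced form
    back to its oxidised partner — the cofactor pool is conserved, so a
    plain sink could never carry flux; for ordinary species it is a simple
    irreversible sink.
    """
    met_ids = model.network.species_compartments(species_key)
    if not met_ids:
        raise ValueError(
            f"species {species_key!r} not present in any compartment"
        )
    oxidised = COFACTOR_PAIRS.get(species_key)
    drains = []
    for met_id in met_ids:
        stoich = {met_id: -1.0}
        if oxidised is not None:
            comp = model.network.metabolite(met_id).compartment
            ox_id = f"{oxidised}[{comp}]"
            if not model.network.has_metabolite(ox_id):
                continue
            stoich[ox_id] = 1.0
        drains.append(
            Reaction(
                id=f"__drain_{met_id}",
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=np.inf,
            )
        )
    if not drains:
        raise ValueError(
            f"no compartment holds both {species_key!r} and {oxidised!r}"
        )
    return drains


def production_capacity(
    model: ContextModel,
    species_key: str,
    return_per_compartment: bool = False,
):
    """Maximal production of a species, summed over its compartments.

    Transient irreversible drains ``met[x] -> ∅`` are added for every
    compartment holding the species and the *sum* of drain fluxes is
    maximised in a single joint optimisation (per-compartment maxima can be
    jointly infeasible, so they are not summed independently).  Returns the
    optimum, or 0.0 with an infeasibility flag if the locked space is empty.
    """
    drains = _drain_reactions(model, species_key)
    prob = model.build_problem(extra_reactions=drains)
    sol = prob.solve({f"v_{d.id}": 1.0 for d in drains}, "max")
    if sol.status == INFEASIBLE:
        result = (0.0, True)
    elif not sol.ok:
        raise InfeasibleError(
            f"production capacity of {species_key!r} is unbounded"
        )
    else:
        result = (max(0.0, sol.objective), False)
    if return_per_compartment:
        per_comp = {}
        if sol.ok:
            for d in drains:
                met_id = next(iter(d.stoichiometry))
                comp = model.network.metabolite(met_id).compartment
                per_comp[comp] = sol.values[f"v_{d.id}"]
        return result + (per_comp,)
    return result[0] if not result[1] else 0.0


def capacity_table(
    model: ContextModel, species_keys: list[str] | None = None
) -> CapacityTable:
    """Production capacities for many species (all, by default)."""
    if species_keys is None:
        seen = set()
        species_keys = []
        for m in model.network.metabolites:
            if m.species_key not in seen:
                seen.add(m.species_key)
                species_keys.append(m.species_key)
    caps: dict[str, float] = {}
    per_comp: dict[tuple[str, str], float] = {}
    infeasible: set[str] = set()
    for key in species_keys:
        cap, infeas, by_comp = production_capacity(
            model, key, return_per_compartment=True
        )
        caps[key] = cap
        if infeas:
            infeasible.add(key)
        for comp, rate in by_comp.items():
            per_comp[(key, comp)] = rate
    return CapacityTable(caps, per_comp, infeasible)


def redox_capacity(
    model: ContextModel,
    nadh_pair: tuple[str, str] = ("nadh", "nad"),
    nadph_pair: tuple[str, str] = ("nadph", "nadp"),
) -> tuple[float, float]:
    """Capacity to regenerate NADH and NADPH from their oxidised forms.

    For each cofactor a transient drain ``reduced[x] -> oxidised[x]`` is
    added in every compartment holding both species and the summed drain
    flux is maximised; this measures how fast the model can produce reducing
    power, not the pool size.  Returns ``(nadh_cap, nadph_cap)``.
    """
    caps = []
    for reduced, oxidised in (nadh_pair, nadph_pair):
        red_ids = model.network.species_compartments(reduced)
        if not red_ids:
            raise ValueError(f"cofactor species {reduced!r} absent from network")
        drains = []
        for red_id in red_ids:
            comp = model.network.metabolite(red_id).compartment
            ox_id = f"{oxidised}[{comp}]"
            if not model.network.has_metabolite(ox_id):
                continue
            drains.append(
                Reaction(
                    id=f"__redox_{red_id}",
                    stoichiometry={red_id: -1.0, ox_id: 1.0},
                    lower_bound=0.0,
                    upper_bound=np.inf,
                )
            )
        if not drains:
            raise ValueError(
                f"no compartment holds both {reduced!r} and {oxidised!r}"
            )
        prob = model.build_problem(extra_reactions=drains)
        sol = prob.solve_or_raise({f"v_{d.id}": 1.0 for d in drains}, "max")
        caps.append(max(0.0, sol.objective))
    return caps[0], caps[1]


def pathway_fold_change(
    cap_a: CapacityTable,
    cap_b: CapacityTable,
    species_pathways: dict[str, str],
    floor: float = CAPACITY_FLOOR,
) -> dict[str, dict]:
    """Median capacity fold-change (a over b) per pathway.

    Species with both capacities below ``floor`` are excluded; a
    below-floor denominator alone is floored and the pathway flagged.  A
    pathway with no usable species gets ``median=None`` with a flag rather
    than raising.
    """
    by_pathway: dict[str, list[float]] = {}
    flagged: dict[str, bool] = {}
    for species, pathway in species_pathways.items():
        if species not in cap_a.capacities or species not in cap_b.capacities:
            continue
        a, b = cap_a.capacities[species], cap_b.capacities[species]
        if a < floor and b < floor:
            continue
        floored = b < floor
        fold = a / max(b, floor)
        by_pathway.setdefault(pathway, []).append(fold)
        flagged[pathway] = flagged.get(pathway, False) or floored
    out: dict[str, dict] = {}
    for pathway in sorted(set(species_pathways.values())):
        folds = by_pathway.get(pathway, [])
        if not folds:
            out[pathway] = {"median": None, "n": 0, "flag": "undefined"}
        else:
            out[pathway] = {
                "median": float(np.median(folds)),
                "n": len(folds),
                "flag": "floored" if flagged.get(pathway) else "",
            }
    return out


def _max_objective(prob: LinearModel, objective_var: str) -> float | None:
    sol = prob.solve({objective_var: 1.0}, "max")
    if sol.status == INFEASIBLE:
        return None
    if not sol.ok:
        raise InfeasibleError(f"objective {objective_var} unbounded")
    return sol.objective


def essentiality_scan(
    model: ContextModel,
    objective_reaction: str,
    viability_fraction: float = 0.01,
    reactions: list[str] | None = None,
) -> set[str]:
    """Reactions whose knockout drops the objective below
    ``viability_fraction`` of its unconstrained maximum."""
    if not model.network.has_reaction(objective_reaction):
        raise ValueError(f"objective reaction {objective_reaction!r} not in network")
    obj_var = f"v_{objective_reaction}"
    base = _max_objective(model.build_problem(), obj_var)
    if base is None:
        raise InfeasibleError("objective infeasible even without knockouts")
    threshold = viability_fraction * base
    if reactions is None:
        reactions = [r.id for r in model.network.reactions]
    essential: set[str] = set()
    for rxn_id in reactions:
        if rxn_id == objective_reaction:
            continue
        prob = model.build_problem()
        # a knockout removes the reaction entirely: its bounds (including a
        # positive lower bound) are overridden, not intersected with v = 0
        prob.set_bounds(f"v_{rxn_id}", 0.0, 0.0)
        best = _max_objective(prob, obj_var)
        if best is None or best < threshold - SOLVER_TOL:
            essential.add(rxn_id)
    return essential


def _capacity_with_constraints(
    model: ContextModel,
    species_key: str,
    extra_constraints: list[tuple[dict[str, float], float, float]],
) -> float | None:
    drains = _drain_reactions(model, species_key)
    prob = model.build_problem(extra_reactions=drains)
    for coefs, lb, ub in extra_constraints:
        prob.add_constr(coefs, lb=lb, ub=ub)
    sol = prob.solve({f"v_{d.id}": 1.0 for d in drains}, "max")
    if sol.status == INFEASIBLE:
        return None
    if not sol.ok:
        raise InfeasibleError(f"capacity of {species_key!r} unbounded")
    return max(0.0, sol.objective)


def coupling_scan(
    model: ContextModel,
    capacity_target: str,
    reactions: list[str] | None = None,
    eps_act: float | None = None,
    reference_reaction: str | None = None,
) -> CouplingScanResult:
    """Target production capacity when each reaction is forced active.

    For every scanned reaction r the constraint |v_r| >= eps is imposed as a
    disjunction solved by two LPs (v_r >= eps, then v_r <= -eps where the
    bounds admit it) keeping the better objective; infeasible forcings are
    flagged with capacity 0.  If ``reference_reaction`` is given (e.g. the
    glutathione-succination sink), the comparison field reports how extreme
    its capacity *decrease* is among all scanned reactions: an empirical
    rank p-value, and a rank-sum test of its decrease against the others'
    decreases.  A single reference value does not determine a unique
    two-sample construction, so both summaries are reported.
    """
    if eps_act is None:
        eps_act = model.eps_act
    unforced = production_capacity(model, capacity_target)
    if reactions is None:
        reactions = [r.id for r in model.network.reactions]
    per_reaction: dict[str, float] = {}
    infeasible: set[str] = set()
    for rxn_id in reactions:
        r = model.network.reaction(rxn_id)
        candidates = []
        if r.upper_bound >= eps_act:
            cap = _capacity_with_constraints(
                model, capacity_target, [({f"v_{rxn_id}": 1.0}, eps_act, np.inf)]
            )
            if cap is not None:
                candidates.append(cap)
        if r.lower_bound <= -eps_act:
            cap = _capacity_with_constraints(
                model, capacity_target, [({f"v_{rxn_id}": 1.0}, -np.inf, -eps_act)]
            )
            if cap is not None:
                candidates.append(cap)
        if candidates:
            per_reaction[rxn_id] = max(candidates)
        else:
            per_reaction[rxn_id] = 0.0
            infeasible.add(rxn_id)
    comparison = None
    if reference_reaction is not None:
        if reference_reaction not in per_reaction:
            raise ValueError(
                f"reference reaction {reference_reaction!r} was not scanned"
            )
        ref_decrease = unforced - per_reaction[reference_reaction]
        other_decreases = [
            unforced - cap
            for rxn_id, cap in per_reaction.items()
            if rxn_id != reference_reaction and rxn_id not in infeasible
        ]
        n_ge = sum(1 for d in other_decreases if d >= ref_decrease - SOLVER_TOL)
        empirical_p = (1 + n_ge) / (1 + len(other_decreases))
        u_stat, rs_p = (
            wilcoxon_ranksum([ref_decrease], other_decreases, alternative="greater")
            if other_decreases
            else (math.nan, math.nan)
        )
        comparison = {
            "reference_decrease": ref_decrease,
            "empirical_rank_p": empirical_p,
            "statistic": u_stat,
            "p_value": rs_p,
            "method": "wilcoxon-ranksum",
        }
    return CouplingScanResult(
        per_reaction=per_reaction,
        infeasible=infeasible,
        reference_reaction=reference_reaction,
        reference_capacity=unforced,
        comparison=comparison,
    )
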