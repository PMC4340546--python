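"""Two-stage construction of context-specific models.

Stage 1 (iMAT): a MILP selects a steady-state flux pattern maximising
agreement with the expression data — each highly-expressed reaction scores
when it carries flux of magnitude at least ``eps_act`` (in either direction),
each lowly-expressed reaction scores when it carries zero flux.

Stage 2 (measured-flux fit): holding the iMAT objective at its optimum, an
LP minimises the total absolute deviation of computed exchange fluxes from
the measured uptake/secretion rates,

    min  sum_i (y+_i + y-_i)
    s.t. S v = 0,  v_min <= v <= v_max,
         v_i - f_i = y+_i - y-_i,  y+, y- >= 0   for each measured i,

the standard exact linearisation of min sum |v_i - f_i|.

Both optima are then *locked*: every downstream analysis (FVA, capacities,
sweeps) explores the space of alternative optima — all flux states attaining
the same agreement with expression and measurements — rather than a single
arbitrary optimal solution.  The expression-agreement lock keeps the boolean
indicator variables in the system, so the space is the union over all
co-optimal iMAT activity patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpr import CATEGORIES, HIGH, LOW, MODERATE, evaluate_gpr
from .lp import InfeasibleError, LinearModel
from .network import MetabolicNetwork, Reaction

#: default flux magnitude that counts as "active" for iMAT scoring
DEFAULT_EPS_ACT = 1.0
#: fallback bound magnitude used when a reaction bound is infinite
DEFAULT_BIG_M = 1000.0
#: relative / absolute slack when locking the deviation optimum
LOCK_REL_TOL = 1e-6
LOCK_ABS_TOL = 1e-6


class ContradictionError(RuntimeError):
    """The locked optima are mutually infeasible (inconsistent inputs)."""


# ---------------------------------------------------------------------------
# expression handling
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Per-gene expression as tri-level categories, optionally with the
    continuous values and quantile thresholds they were derived from."""

    categories: dict[str, str]
    values: dict[str, float] | None = None
    thresholds: tuple[float, float] | None = None

    def __post_init__(self):
        for g, c in self.categories.items():
            if c not in CATEGORIES:
                raise ValueError(f"gene {g!r}: unknown category {c!r}")


@dataclass
class ReactionCategories:
    """Tri-level activity category per reaction (via its GPR)."""

    categories: dict[str, str]

    def __getitem__(self, rxn_id: str) -> str:
        return self.categories[rxn_id]

    def items(self):
        return self.categories.items()

    def of(self, category: str) -> list[str]:
        return [r for r, c in self.categories.items() if c == category]


@dataclass
class FluxMeasurementSet:
    """Measured exchange rates f_i (positive = secretion, negative = uptake)."""

    measurements: dict[str, float]

    def validate_against(self, network: MetabolicNetwork) -> None:
        exchanges = set(network.exchange_reactions())
        bad = sorted(set(self.measurements) - exchanges)
        if bad:
            raise ValueError(
                f"measured reactions are not exchanges of the network: {bad}"
            )

    def without(self, rxn_id: str) -> "FluxMeasurementSet":
        return FluxMeasurementSet(
            {r: f for r, f in self.measurements.items() if r != rxn_id}
        )

    def __len__(self) -> int:
        return len(self.measurements)


def discretize_expression(
    values: dict[str, float],
    low_q: float = 0.25,
    high_q: float = 0.75,
) -> ExpressionProfile:
    """Tri-level discretisation by quantile thresholds.

    A gene is HIGH if its value is strictly above the ``high_q`` quantile,
    LOW if strictly below the ``low_q`` quantile, MODERATE otherwise; values
    tied with a threshold are MODERATE (conservative, deterministic).
    """
    if not values:
        raise ValueError("empty expression profile")
    if not (0.0 <= low_q < high_q <= 1.0):
        raise ValueError(f"require 0 <= low_q < high_q <= 1, got {low_q}, {high_q}")
    arr = np.array(list(values.values()), dtype=float)
    lo_thr = float(np.quantile(arr, low_q))
    hi_thr = float(np.quantile(arr, high_q))
    categories = {}
    for gene, val in values.items():
        if val > hi_thr:
            categories[gene] = HIGH
        elif val < lo_thr:
            categories[gene] = LOW
        else:
            categories[gene] = MODERATE
    return ExpressionProfile(categories, dict(values), (lo_thr, hi_thr))


def map_expression_to_reactions(
    network: MetabolicNetwork, profile: ExpressionProfile
) -> ReactionCategories:
    """Push gene categories through each reaction's GPR (AND=min, OR=max)."""
    out = {}
    for r in network.reactions:
        if not r.gpr.strip():
            out[r.id] = MODERATE
        else:
            try:
                out[r.id] = evaluate_gpr(r.gpr, profile.categories)
            except ValueError as exc:
                raise ValueError(f"reaction {r.id!r}: {exc}") from exc
    return ReactionCategories(out)


# ---------------------------------------------------------------------------
# MILP construction
# ---------------------------------------------------------------------------

def _clamp(value: float, big_m: float) -> float:
    if np.isinf(value):
        return np.sign(value) * big_m
    return value


def _add_flux_variables(
    model: LinearModel, reactions: list[Reaction]
) -> None:
    for r in reactions:
        model.add_var(f"v_{r.id}", r.lower_bound, r.upper_bound)


def _add_mass_balance(
    model: LinearModel,
    network: MetabolicNetwork,
    extra_reactions: list[Reaction] = (),
) -> None:
    rows: dict[str, dict[str, float]] = {m.id: {} for m in network.metabolites}
    for r in list(network.reactions) + list(extra_reactions):
        for met_id, coef in r.stoichiometry.items():
            rows[met_id][f"v_{r.id}"] = rows[met_id].get(f"v_{r.id}", 0.0) + coef
    for met_id, row in rows.items():
        if row:
            model.add_constr(row, lb=0.0, ub=0.0)


def _add_imat_indicators(
    model: LinearModel,
    network: MetabolicNetwork,
    categories: ReactionCategories,
    eps_act: float,
    big_m: float,
) -> list[str]:
    """Add iMAT boolean indicators; returns the indicator variable names.

    A HIGH reaction gets forward/reverse activity indicators (only for
    directions its bounds admit at eps_act); a LOW reaction gets a
    zero-flux indicator.  The iMAT objective is the sum of indicators.
    """
    indicators: list[str] = []
    for rxn_id, cat in sorted(categories.items()):
        if not network.has_reaction(rxn_id):
            raise ValueError(f"categorised reaction {rxn_id!r} not in network")
        r = network.reaction(rxn_id)
        lb = _clamp(r.lower_bound, big_m)
        ub = _clamp(r.upper_bound, big_m)
        v = f"v_{rxn_id}"
        if cat == HIGH:
            direction_vars = []
            if ub >= eps_act:
                hf = model.add_var(f"hf_{rxn_id}", binary=True)
                # hf = 1  =>  v >= eps_act
                model.add_constr({v: 1.0, hf: lb - eps_act}, lb=lb)
                direction_vars.append(hf)
            if lb <= -eps_act:
                hr = model.add_var(f"hr_{rxn_id}", binary=True)
                # hr = 1  =>  v <= -eps_act
                model.add_constr({v: 1.0, hr: ub + eps_act}, ub=ub)
                direction_vars.append(hr)
            if len(direction_vars) == 2:
                model.add_constr({d: 1.0 for d in direction_vars}, ub=1.0)
            indicators.extend(direction_vars)
        elif cat == LOW:
            z = model.add_var(f"z_{rxn_id}", binary=True)
            # z = 1  =>  v = 0
            model.add_constr({v: 1.0, z: ub}, ub=ub)
            model.add_constr({v: 1.0, z: lb}, lb=lb)
            indicators.append(z)
    return indicators


def _add_deviation_variables(
    model: LinearModel, measurements: FluxMeasurementSet
) -> list[str]:
    """Add y+/y- split deviation variables; returns their names."""
    names: list[str] = []
    for rxn_id, f_i in sorted(measurements.measurements.items()):
        yp = model.add_var(f"yplus_{rxn_id}", lb=0.0)
        ym = model.add_var(f"yminus_{rxn_id}", lb=0.0)
        # v_i - f_i = y+ - y-
        model.add_constr(
            {f"v_{rxn_id}": 1.0, yp: -1.0, ym: 1.0}, lb=f_i, ub=f_i
        )
        names.extend([yp, ym])
    return names


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def solve_imat(
    network: MetabolicNetwork,
    categories: ReactionCategories,
    eps_act: float = DEFAULT_EPS_ACT,
    big_m: float = DEFAULT_BIG_M,
) -> tuple[dict[str, str], int]:
    """Solve the iMAT MILP; returns (activity assignment, optimal count).

    The assignment labels each categorised reaction ACTIVE_FWD, ACTIVE_REV,
    INACTIVE or FREE in one (arbitrary but deterministic) optimal solution;
    only the optimal count is meant to constrain downstream analyses.
    """
    if eps_act <= 0:
        raise ValueError("eps_act must be positive")
    model = LinearModel()
    _add_flux_variables(model, network.reactions)
    _add_mass_balance(model, network)
    indicators = _add_imat_indicators(model, network, categories, eps_act, big_m)
    if not indicators:
        # no HIGH/LOW reactions: any feasible flux is optimal with score 0
        sol = model.solve({}, "min")
        if not sol.ok:
            raise InfeasibleError("network has no steady-state flux solution")
        return {r: "FREE" for r, _ in categories.items()}, 0
    sol = model.solve({i: 1.0 for i in indicators}, "max")
    if not sol.ok:
        raise InfeasibleError("network has no steady-state flux solution")
    assignment: dict[str, str] = {}
    for rxn_id, cat in categories.items():
        if cat == HIGH:
            if sol.values.get(f"hf_{rxn_id}", 0.0) > 0.5:
                assignment[rxn_id] = "ACTIVE_FWD"
            elif sol.values.get(f"hr_{rxn_id}", 0.0) > 0.5:
                assignment[rxn_id] = "ACTIVE_REV"
            else:
                assignment[rxn_id] = "FREE"
        elif cat == LOW:
            assignment[rxn_id] = (
                "INACTIVE" if sol.values.get(f"z_{rxn_id}", 0.0) > 0.5 else "FREE"
            )
        else:
            assignment[rxn_id] = "FREE"
    return assignment, int(round(sol.objective))


@dataclass
class ContextModel:
    """A network with locked expression-agreement and measured-flux-deviation
    optima; the object all FVA-type analyses explore."""

    network: MetabolicNetwork
    reaction_categories: ReactionCategories = field(
        default_factory=lambda: ReactionCategories({})
    )
    measurements: FluxMeasurementSet = field(
        default_factory=lambda: FluxMeasurementSet({})
    )
    imat_optimum: int = 0
    deviation_optimum: float = 0.0
    eps_act: float = DEFAULT_EPS_ACT
    big_m: float = DEFAULT_BIG_M
    lock_rel_tol: float = LOCK_REL_TOL
    lock_abs_tol: float = LOCK_ABS_TOL

    @classmethod
    def from_network(cls, network: MetabolicNetwork) -> "ContextModel":
        """An unlocked context: plain steady-state space with bounds."""
        return cls(network)

    @property
    def deviation_lock(self) -> float:
        return self.deviation_optimum * (1.0 + self.lock_rel_tol) + self.lock_abs_tol

    def build_problem(
        self, extra_reactions: list[Reaction] = ()
    ) -> LinearModel:
        """Materialise the locked feasible space as a solver model.

        ``extra_reactions`` (e.g. transient production drains) receive flux
        variables and enter the mass-balance rows but not the locks.
        Idempotent: each call builds a fresh model.
        """
        model = LinearModel()
        _add_flux_variables(model, list(self.network.reactions) + list(extra_reactions))
        _add_mass_balance(model, self.network, extra_reactions)
        if self.reaction_categories.categories:
            indicators = _add_imat_indicators(
                model, self.network, self.reaction_categories, self.eps_act, self.big_m
            )
            if indicators and self.imat_optimum > 0:
                model.add_constr(
                    {i: 1.0 for i in indicators}, lb=float(self.imat_optimum)
                )
        if self.measurements.measurements:
            deviations = _add_deviation_variables(model, self.measurements)
            model.add_constr(
                {d: 1.0 for d in deviations}, ub=self.deviation_lock
            )
        return model

    def is_locked(self) -> bool:
        return bool(self.reaction_categories.categories) or bool(
            self.measurements.measurements
        )


def fit_fluxes(
    network: MetabolicNetwork,
    categories: ReactionCategories,
    imat_optimum: int,
    measurements: FluxMeasurementSet,
    eps_act: float = DEFAULT_EPS_ACT,
    big_m: float = DEFAULT_BIG_M,
) -> ContextModel:
    """Stage-2 LP: minimal L1 deviation from measured exchange rates under
    the locked iMAT optimum; returns the fully locked context model."""
    measurements.validate_against(network)
    model = LinearModel()
    _add_flux_variables(model, network.reactions)
    _add_mass_balance(model, network)
    indicators = _add_imat_indicators(model, network, categories, eps_act, big_m)
    if indicators and imat_optimum > 0:
        model.add_constr({i: 1.0 for i in indicators}, lb=float(imat_optimum))
    deviations = _add_deviation_variables(model, measurements)
    sol = model.solve({d: 1.0 for d in deviations}, "min")
    if not sol.ok:
        raise ContradictionError(
            "locked expression-agreement space is infeasible; the iMAT "
            f"optimum {imat_optimum} (eps_act={eps_act}) cannot be attained "
            "together with mass balance and bounds"
        )
    d_star = max(0.0, float(sol.objective))
    return ContextModel(
        network=network,
        reaction_categories=categories,
        measurements=measurements,
        imat_optimum=imat_optimum,
        deviation_optimum=d_star,
        eps_act=eps_act,
        big_m=big_m,
    )


def build_context(
    network: MetabolicNetwork,
    profile: ExpressionProfile,
    measurements: FluxMeasurementSet,
    low_q: float = 0.25,
    high_q: float = 0.75,
    eps_act: float = DEFAULT_EPS_ACT,
    big_m: float = DEFAULT_BIG_M,
) -> ContextModel:
    """Convenience wrapper running both construction stages in order."""
    categories = map_expression_to_reactions(network, profile)
    _, optimum = solve_imat(network, categories, eps_act, big_m)
    return fit_fluxes(network, categories, optimum, measurements, eps_act, big_m)
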