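"""Glutathione succination and the exchange-flux dependency scan.

Fumarate reacts non-enzymatically with the thiol of reduced glutathione to
form the adduct succinicGSH (S-(1,2-dicarboxyethyl)glutathione).  This
module inserts that chemistry into a network — one irreversible
``gsh[x] + fum[x] -> succgsh`` reaction per compartment holding both
substrates, plus a secretion sink for the adduct — and provides the
dependency scan that correlates a metabolite's exchange flux with the
model's maximal glutathione production.  In an FH-deficient context the
sink carries a forced minimum flux, representing constitutive succination
driven by accumulated fumarate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .capacity import SOLVER_TOL, _capacity_with_constraints, run_fva
from .context import ContextModel
from .network import MetabolicNetwork, Metabolite, Reaction
from .stats import spearman

#: default forced secretion of the adduct in the FH-deficient variant
DEFAULT_EPS_SEC = 0.01


@dataclass
class SuccinationSpec:
    """Where to graft the succination reactions and how hard to force them."""

    gsh_species: str = "gsh"
    fum_species: str = "fum"
    succgsh_id: str = "succgsh"
    compartments: tuple[str, ...] = ("c", "m")
    sink_min_flux: float = 0.0  # > 0 only for the FH-deficient variant
    sink_max_flux: float = 1000.0
    added_reaction_ids: list[str] = field(default_factory=list)


def add_succination(
    network: MetabolicNetwork, spec: SuccinationSpec
) -> MetabolicNetwork:
    """Return a new network with the succination reactions grafted in.

    The adduct is modelled as a single pooled species without a compartment
    tag; its sink is an exchange (secretion) whose lower bound is
    ``spec.sink_min_flux``.  The input network is not modified.
    """
    if network.has_metabolite(spec.succgsh_id):
        raise ValueError(
            f"metabolite id {spec.succgsh_id!r} already present in network"
        )
    added: list[Reaction] = []
    usable: list[str] = []
    for comp in spec.compartments:
        gsh_id = f"{spec.gsh_species}[{comp}]"
        fum_id = f"{spec.fum_species}[{comp}]"
        if network.has_metabolite(gsh_id) and network.has_metabolite(fum_id):
            usable.append(comp)
            added.append(
                Reaction(
                    id=f"SUCCINATION_{comp}",
                    stoichiometry={gsh_id: -1.0, fum_id: -1.0, spec.succgsh_id: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    pathway="glutathione succination",
                )
            )
    if not usable:
        raise ValueError(
            f"no compartment in {spec.compartments} holds both "
            f"{spec.gsh_species!r} and {spec.fum_species!r}"
        )
    if len(usable) < len(spec.compartments):
        missing = sorted(set(spec.compartments) - set(usable))
        warnings.warn(
            f"succination added only in {usable}; compartment(s) {missing} "
            "lack one of the substrates",
            stacklevel=2,
        )
    sink = Reaction(
        id="SUCCGSH_SINK",
        stoichiometry={spec.succgsh_id: -1.0},
        lower_bound=spec.sink_min_flux,
        upper_bound=spec.sink_max_flux,
        is_exchange=True,
        pathway="glutathione succination",
    )
    added.append(sink)
    for r in added:
        if network.has_reaction(r.id):
            raise ValueError(f"reaction id {r.id!r} already present in network")
    spec.added_reaction_ids = [r.id for r in added]
    return network.with_reactions(
        added=added,
        added_metabolites=[
            Metabolite(id=spec.succgsh_id, name="succinicGSH", compartment="")
        ],
    )


@dataclass
class SweepResult:
    exchange_reaction: str
    grid: list[tuple[float, float]]  # (pinned exchange flux, max target production)
    fva_range: tuple[float, float]
    rho: float
    p_value: float
    flag: str = ""  # "", "degenerate-range", "constant-production"
    method: str = "spearman"


def exchange_sweep(
    model: ContextModel,
    exchange_id: str,
    target: str,
    n_points: int = 20,
    tol: float = SOLVER_TOL,
) -> SweepResult:
    """Dependency of a species' maximal production on one exchange flux.

    The exchange's feasible range [lo, hi] is found by FVA; the exchange
    flux is then stepped through ``n_points`` evenly spaced values spanning
    the range (pinned at each value), and the maximal production of
    ``target`` is recorded at each step.  The result carries the Spearman
    correlation between the stepped flux values and the production maxima:
    negative means uptake of the metabolite feeds target production
    (cystine-like), positive that higher exchange flux — less uptake or
    more secretion — frees the model to produce more (arginine-like).
    """
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    rxn = model.network.reaction(exchange_id)
    if not rxn.is_exchange:
        raise ValueError(f"{exchange_id!r} is not an exchange reaction")
    (fva,) = run_fva(model, [exchange_id])
    lo, hi = fva.min_flux, fva.max_flux
    if hi - lo < tol:
        return SweepResult(
            exchange_id, [], (lo, hi), math.nan, math.nan, flag="degenerate-range"
        )
    grid: list[tuple[float, float]] = []
    for i in range(n_points):
        b = lo + (hi - lo) * i / (n_points - 1)
        cap = _capacity_with_constraints(
            model, target, [({f"v_{exchange_id}": 1.0}, b, b)]
        )
        if cap is None:
            continue  # non-convex locked space: a pinned level can be infeasible
        grid.append((b, cap))
    caps = [c for _, c in grid]
    if len(grid) < 3 or max(caps) - min(caps) < tol:
        return SweepResult(
            exchange_id, grid, (lo, hi), math.nan, math.nan,
            flag="constant-production",
        )
    res = spearman([b for b, _ in grid], caps, exact_n=10)
    flag = "undefined-correlation" if res.undefined else ""
    return SweepResult(
        exchange_id, grid, (lo, hi), res.statistic, res.p_value, flag=flag
    )


def dependency_report(
    model: ContextModel,
    exchanges: list[str] | None = None,
    target: str = "gsh",
    n_points: int = 20,
) -> pd.DataFrame:
    """Run :func:`exchange_sweep` for each exchange; one row per exchange.

    Per-exchange degeneracies are reported as flags; a single degenerate
    exchange never aborts the scan.
    """
    if exchanges is None:
        exchanges = model.network.exchange_reactions()
    rows = []
    sweeps: dict[str, SweepResult] = {}
    for ex in exchanges:
        res = exchange_sweep(model, ex, target, n_points=n_points)
        sweeps[ex] = res
        rows.append(
            {
                "exchange": ex,
                "fva_min": res.fva_range[0],
                "fva_max": res.fva_range[1],
                "rho": res.rho,
                "p_value": res.p_value,
                "flag": res.flag,
            }
        )
    df = pd.DataFrame(
        rows, columns=["exchange", "fva_min", "fva_max", "rho", "p_value", "flag"]
    )
    df.attrs["sweeps"] = sweeps
    df.attrs["target"] = target
    return df
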