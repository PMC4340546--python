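"""Shared fixtures and independent oracles.

The oracles here deliberately bypass the package's solver layer: they call
``scipy.optimize.linprog`` directly on explicitly constructed matrices, so
that agreement between package results and oracle results is a genuine
cross-check of two code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from contextflux import MetabolicNetwork, Metabolite, Reaction


def make_chain_network(uptake_max: float = 10.0) -> MetabolicNetwork:
    """EX_A (uptake) -> A -> B -> EX_B (secretion), single path."""
    mets = [Metabolite(id="A[c]"), Metabolite(id="B[c]")]
    rxns = [
        Reaction("EX_A", {"A[c]": -1.0}, -uptake_max, 0.0, is_exchange=True),
        Reaction("AB", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0),
        Reaction("EX_B", {"B[c]": -1.0}, 0.0, 1000.0, is_exchange=True),
    ]
    return MetabolicNetwork(mets, rxns)


@pytest.fixture
def chain_network() -> MetabolicNetwork:
    return make_chain_network()


def _network_arrays(network: MetabolicNetwork):
    S = network.stoichiometric_matrix().toarray()
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    index = {r.id: j for j, r in enumerate(network.reactions)}
    return S, bounds, index


def lp_feasible(network: MetabolicNetwork, bound_overrides: dict) -> bool:
    """Is {S v = 0, bounds (with overrides)} non-empty?  Direct linprog call."""
    S, bounds, index = _network_arrays(network)
    for rid, (lo, hi) in bound_overrides.items():
        if lo > hi:
            return False
        bounds[index[rid]] = (lo, hi)
    res = linprog(
        c=np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=bounds, method="highs",
    )
    return res.status == 0


def lp_optimize(
    network: MetabolicNetwork,
    objective: dict[str, float],
    sense: str = "max",
    bound_overrides: dict | None = None,
    extra_eq: list[tuple[dict[str, float], float]] | None = None,
):
    """Optimise a linear objective over {S v = 0, bounds}; returns
    (value, flux dict) or None if infeasible."""
    S, bounds, index = _network_arrays(network)
    for rid, (lo, hi) in (bound_overrides or {}).items():
        if lo > hi:
            return None
        bounds[index[rid]] = (lo, hi)
    c = np.zeros(S.shape[1])
    for rid, coef in objective.items():
        c[index[rid]] = coef
    if sense == "max":
        c = -c
    a_eq, b_eq = [S], [np.zeros(S.shape[0])]
    for coefs, rhs in extra_eq or []:
        row = np.zeros(S.shape[1])
        for rid, coef in coefs.items():
            row[index[rid]] = coef
        a_eq.append(row[None, :])
        b_eq.append([rhs])
    res = linprog(
        c=c, A_eq=np.vstack(a_eq), b_eq=np.concatenate(b_eq),
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        return None
    value = float(res.fun) if sense == "min" else -float(res.fun)
    flux = {r.id: float(res.x[j]) for r, j in zip(network.reactions, index.values())}
    return value, flux


def imat_bruteforce(
    network: MetabolicNetwork, categories: dict[str, str], eps: float
) -> int:
    """Exhaustive iMAT optimum: enumerate every HIGH/LOW satisfaction
    pattern and check each with one feasibility LP."""
    high = sorted(r for r, c in categories.items() if c == "HIGH")
    low = sorted(r for r, c in categories.items() if c == "LOW")
    best = 0
    high_opts = [("fwd", "rev", "none")] * len(high)
    low_opts = [("zero", "none")] * len(low)
    for combo in itertools.product(*(high_opts + low_opts)):
        overrides = {}
        score = 0
        ok = True
        for rid, choice in zip(high + low, combo):
            r = network.reaction(rid)
            lo, hi = r.lower_bound, r.upper_bound
            if choice == "fwd":
                lo = max(lo, eps)
                score += 1
            elif choice == "rev":
                hi = min(hi, -eps)
                score += 1
            elif choice == "zero":
                lo, hi = 0.0, 0.0
                score += 1
            if lo > hi:
                ok = False
                break
            overrides[rid] = (lo, hi)
        if not ok or score <= best:
            continue
        if lp_feasible(network, overrides):
            best = score
    return best


def knockout_bruteforce(
    network: MetabolicNetwork, objective_reaction: str, viability_fraction: float
) -> set[str]:
    """Essential reactions by direct single-knockout LPs."""
    base = lp_optimize(network, {objective_reaction: 1.0}, "max")
    assert base is not None
    threshold = viability_fraction * base[0]
    essential = set()
    for r in network.reactions:
        if r.id == objective_reaction:
            continue
        res = lp_optimize(
            network, {objective_reaction: 1.0}, "max",
            bound_overrides={r.id: (0.0, 0.0)},
        )
        if res is None or res[0] < threshold - 1e-6:
            essential.add(r.id)
    return essential


def random_categories(
    network: MetabolicNetwork, rng: np.random.Generator, max_labels: int = 4
) -> dict[str, str]:
    """Random HIGH/LOW labels on at most ``max_labels`` reactions."""
    rxn_ids = [r.id for r in network.reactions]
    k = int(rng.integers(1, min(max_labels, len(rxn_ids)) + 1))
    chosen = rng.choice(len(rxn_ids), size=k, replace=False)
    return {
        rxn_ids[i]: ("HIGH" if rng.random() < 0.5 else "LOW") for i in chosen
    }
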