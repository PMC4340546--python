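"""Seeded synthetic scenarios with planted ground truth.

The toy network emulates, at desk scale, the redox wiring the analyses
probe: a glucose-like carbon input feeding a pentose-phosphate-like NADPH
source, cystine uptake reduced to cysteine at NADPH expense, glutathione
synthesis from cysteine (co-exporting an arginine-like byproduct),
glutamine-driven fumarate production in the mitochondrion with an FH
(fumarate hydratase) reaction that the knockout variant removes, a silent
methionine-to-cysteine alternative route, and optional decoy chains that
vary across seeds.  Every scenario carries a planted steady-state flux
vector, per-gene expression truth consistent with it, and generator
metadata; measurements and expression profiles are derived from the truth
with seeded noise.

These toys reproduce the *structure* the analyses rely on (compartments,
exchange conventions, GPRs, a redox-coupled glutathione branch), not the
scale or content of genome-scale human reconstructions.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .context import ExpressionProfile, FluxMeasurementSet
from .gpr import HIGH, LOW, MODERATE, CATEGORIES
from .network import (
    FluxVector,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    network_to_dict,
    write_network,
)

DEFAULT_EPS_ACT = 1.0


@dataclass
class SyntheticScenario:
    """A toy network plus its planted ground truth."""

    network: MetabolicNetwork
    planted_flux: FluxVector
    expression_truth: dict[str, str]  # gene -> category
    gene_reactions: dict[str, str]  # gene -> reaction carrying it
    seed: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "network": network_to_dict(self.network),
            "planted_flux": {k: self.planted_flux.rates[k]
                             for k in sorted(self.planted_flux.rates)},
            "expression_truth": {k: self.expression_truth[k]
                                 for k in sorted(self.expression_truth)},
            "seed": self.seed,
            "metadata": self.metadata,
        }


def _mk(rid, stoich, lb, ub, gpr="", pathway="", exchange=False) -> Reaction:
    return Reaction(
        id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
        gpr=gpr, pathway=pathway, is_exchange=exchange,
    )


def _expression_truth(
    reactions: list[Reaction],
    flux: dict[str, float],
    rng: np.random.Generator,
    eps_act: float,
    p_high: float = 0.8,
) -> tuple[dict[str, str], dict[str, str]]:
    """Assign per-gene categories consistent with the planted flux:
    LOW genes sit on zero-flux reactions, HIGH genes only on reactions
    carrying at least eps_act."""
    truth: dict[str, str] = {}
    gene_rxn: dict[str, str] = {}
    from .gpr import gpr_genes

    for r in reactions:
        if not r.gpr:
            continue
        v = flux.get(r.id, 0.0)
        if v == 0.0:
            cat = LOW
        elif abs(v) >= eps_act and rng.random() < p_high:
            cat = HIGH
        else:
            cat = MODERATE
        for gene in sorted(gpr_genes(r.gpr)):
            truth[gene] = cat
            gene_rxn[gene] = r.id
    return truth, gene_rxn


def make_toy_network(
    seed: int = 0,
    n_decoy_chains: int = 5,
    fh_knockout: bool = False,
    gsh_branch: bool = True,
    glc_max: float = 10.0,
    gln_max: float = 10.0,
    cys2_max: float = 3.0,
    met_max: float = 5.0,
    fh_min_flux: float = 1.0,
    eps_act: float = DEFAULT_EPS_ACT,
    met_branch: bool | None = None,
) -> SyntheticScenario:
    """Build a seeded toy scenario (deterministic for a given seed).

    ``fh_knockout`` removes the fumarate-hydratase reaction (its constitutive
    lower bound ``fh_min_flux`` models FH activity in the wild-type twin), so
    the knockout accumulates fumarate structurally.  ``gsh_branch=False``
    omits the glutathione arm (carbon and decoy chains only).

    ``met_branch`` controls the methionine-to-cysteine salvage route.  By
    default it is present only in the wild-type twin: the FH-deficient
    scenario encodes the cystine-dependent glutathione phenotype (its
    glutathione synthesis draws cysteine exclusively from NADPH-consuming
    cystine reduction), which is the structural dependence the dependency
    and redox analyses are designed to detect.
    """
    if not gsh_branch and n_decoy_chains == 0:
        raise ValueError("a scenario needs the glutathione branch or decoys")
    rng = np.random.default_rng(seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    flux: dict[str, float] = {}

    def met(mid, name="", formula=None):
        mets.append(Metabolite(id=mid, name=name, formula=formula))

    # -- carbon / NADPH arm -------------------------------------------
    for mid in ("glc[e]", "glc[c]", "p5p[c]", "nadp[c]", "nadph[c]"):
        met(mid)
    g = float(rng.uniform(3.0, 8.0))
    rxns += [
        _mk("EX_glc", {"glc[e]": -1.0}, -glc_max, 0.0, exchange=True),
        _mk("GLCt", {"glc[e]": -1.0, "glc[c]": 1.0}, 0.0, 1000.0,
            gpr="g_glct", pathway="transport"),
        _mk("PPP", {"glc[c]": -1.0, "nadp[c]": -2.0,
                    "p5p[c]": 1.0, "nadph[c]": 2.0}, 0.0, 1000.0,
            gpr="g_ppp", pathway="pentose phosphate"),
        _mk("BIOMASS", {"p5p[c]": -1.0}, 0.0, 1000.0, pathway="biomass"),
        _mk("NADPHOX", {"nadph[c]": -1.0, "nadp[c]": 1.0}, 0.0, 1000.0,
            gpr="g_nadphox", pathway="redox"),
    ]
    flux |= {"EX_glc": -g, "GLCt": g, "PPP": g, "BIOMASS": g}

    if met_branch is None:
        met_branch = not fh_knockout
    c = 0.0
    q = 0.0
    if gsh_branch:
        for mid in (
            "gln[e]", "gln[c]", "cys2[e]", "cys2[c]", "cys[c]",
            "gsh[c]", "gsh[m]", "byp[c]", "byp[e]",
            "fum[c]", "fum[m]", "fum[e]", "mal[m]", "oaa[m]",
            "nad[m]", "nadh[m]",
        ):
            met(mid)
        if met_branch:
            met("met[e]")
            met("met[c]")
        c = float(rng.uniform(1.0, cys2_max))  # cystine uptake
        q = float(rng.uniform(1.5, 3.0))  # glutaminolysis-to-fumarate flux
        rxns += [
            _mk("EX_gln", {"gln[e]": -1.0}, -gln_max, 0.0, exchange=True),
            _mk("GLNt", {"gln[e]": -1.0, "gln[c]": 1.0}, 0.0, 1000.0,
                gpr="g_glnt", pathway="transport"),
            _mk("EX_cys2", {"cys2[e]": -1.0}, -cys2_max, 0.0, exchange=True),
            _mk("CYS2t", {"cys2[e]": -1.0, "cys2[c]": 1.0}, 0.0, 1000.0,
                gpr="g_cys2t", pathway="transport"),
            # cystine reduction to two cysteines at NADPH expense
            _mk("CYS2R", {"cys2[c]": -1.0, "nadph[c]": -1.0,
                          "cys[c]": 2.0, "nadp[c]": 1.0}, 0.0, 1000.0,
                gpr="g_cys2r_a and g_cys2r_b", pathway="glutathione"),
            # glutathione synthesis, co-exporting an arginine-like byproduct
            _mk("GSHS", {"cys[c]": -1.0, "gln[c]": -1.0,
                         "gsh[c]": 1.0, "byp[c]": 1.0}, 0.0, 1000.0,
                gpr="g_gshs", pathway="glutathione"),
            _mk("BYPt", {"byp[c]": -1.0, "byp[e]": 1.0}, 0.0, 1000.0,
                gpr="g_bypt", pathway="transport"),
            _mk("EX_byp", {"byp[e]": -1.0}, 0.0, 1000.0, exchange=True),
            _mk("GSHt", {"gsh[c]": -1.0, "gsh[m]": 1.0}, -1000.0, 1000.0,
                gpr="g_gsht", pathway="transport"),
            _mk("SINK_gsh_c", {"gsh[c]": -1.0}, 0.0, 1000.0,
                pathway="glutathione"),
            _mk("SINK_gsh_m", {"gsh[m]": -1.0}, 0.0, 1000.0,
                pathway="glutathione"),
            # glutaminolysis lumped to mitochondrial fumarate + NADH
            _mk("GLS", {"gln[c]": -1.0, "nad[m]": -1.0,
                        "fum[m]": 1.0, "nadh[m]": 1.0}, 0.0, 1000.0,
                gpr="g_gls", pathway="TCA"),
            _mk("NADHD", {"nadh[m]": -1.0, "nad[m]": 1.0}, 0.0, 1000.0,
                gpr="g_nadhd", pathway="oxphos"),
            _mk("FUMt", {"fum[m]": -1.0, "fum[c]": 1.0}, -1000.0, 1000.0,
                gpr="g_fumt", pathway="transport"),
            _mk("FUMte", {"fum[c]": -1.0, "fum[e]": 1.0}, 0.0, 1000.0,
                gpr="g_fumte", pathway="transport"),
            _mk("EX_fum", {"fum[e]": -1.0}, 0.0, 1000.0, exchange=True),
            _mk("MDH", {"mal[m]": -1.0, "nad[m]": -1.0,
                        "oaa[m]": 1.0, "nadh[m]": 1.0}, 0.0, 1000.0,
                gpr="g_mdh", pathway="TCA"),
            _mk("SINK_oaa", {"oaa[m]": -1.0}, 0.0, 1000.0, pathway="TCA"),
        ]
        if met_branch:
            # silent methionine route to cysteine
            rxns += [
                _mk("EX_met", {"met[e]": -1.0}, -met_max, 0.0, exchange=True),
                _mk("METt", {"met[e]": -1.0, "met[c]": 1.0}, 0.0, 1000.0,
                    gpr="g_mett", pathway="transport"),
                _mk("MET2CYS", {"met[c]": -1.0, "cys[c]": 1.0}, 0.0, 1000.0,
                    gpr="g_met2cys", pathway="glutathione"),
            ]
            flux |= {"EX_met": 0.0, "METt": 0.0, "MET2CYS": 0.0}
        if not fh_knockout:
            rxns.append(
                _mk("FH", {"fum[m]": -1.0, "mal[m]": 1.0},
                    fh_min_flux, 1000.0, gpr="g_fh", pathway="TCA")
            )
        fh = 0.0 if fh_knockout else fh_min_flux
        flux |= {
            "EX_cys2": -c, "CYS2t": c, "CYS2R": c,
            "GSHS": 2 * c, "BYPt": 2 * c, "EX_byp": 2 * c,
            "GSHt": 1.0, "SINK_gsh_c": 2 * c - 1.0, "SINK_gsh_m": 1.0,
            "EX_gln": -(2 * c + q), "GLNt": 2 * c + q, "GLS": q,
            "FUMt": q - fh, "FUMte": q - fh, "EX_fum": q - fh,
            "MDH": fh, "SINK_oaa": fh, "NADHD": q + fh,
            "NADPHOX": 2 * g - c,
        }
        if not fh_knockout:
            flux["FH"] = fh
    else:
        flux["NADPHOX"] = 2 * g

    # -- decoy chains --------------------------------------------------
    for j in range(n_decoy_chains):
        e_id, c_id = f"dcy{j}[e]", f"dcy{j}[c]"
        met(e_id)
        met(c_id)
        u = 0.0 if rng.random() < 0.3 else float(rng.uniform(1.5, 5.0))
        rxns += [
            _mk(f"EX_dcy{j}", {e_id: -1.0}, -10.0, 1000.0, exchange=True),
            _mk(f"DCYt{j}", {e_id: -1.0, c_id: 1.0}, 0.0, 1000.0,
                gpr=f"g_dcyt{j}", pathway="decoy"),
            _mk(f"SINK_dcy{j}", {c_id: -1.0}, 0.0, 1000.0, pathway="decoy"),
        ]
        flux |= {f"EX_dcy{j}": -u, f"DCYt{j}": u, f"SINK_dcy{j}": u}

    if not 3 <= len(rxns) <= 200:
        raise ValueError(f"toy network size {len(rxns)} outside [3, 200]")
    network = MetabolicNetwork(mets, rxns, biomass_reaction="BIOMASS")
    planted = FluxVector(dict(flux), feasible=True)
    assert network.check_flux(planted), "planted flux must be steady-state"
    truth, gene_rxn = _expression_truth(rxns, flux, rng, eps_act)
    return SyntheticScenario(
        network=network,
        planted_flux=planted,
        expression_truth=truth,
        gene_reactions=gene_rxn,
        seed=seed,
        metadata={
            "generator": "make_toy_network",
            "n_reactions": len(rxns),
            "n_decoy_chains": n_decoy_chains,
            "compartments": ["c", "m", "e"],
            "gsh_branch": gsh_branch,
            "met_branch": met_branch,
            "fh_knockout": fh_knockout,
            "fh_min_flux": fh_min_flux,
            "eps_act": eps_act,
            "sampled": {"glc_uptake": g, "cys2_uptake": c, "gls_flux": q},
        },
    )


def make_conservation_network(
    n_exchanges: int = 10,
    seed: int = 0,
    n_pools: int = 3,
    bound: float = 50.0,
) -> SyntheticScenario:
    """A fully measurement-determined fixture for cross-validation.

    Exchanges are partitioned round-robin over ``n_pools`` independently
    balanced pools; within each pool steady state forces the exchange fluxes
    to sum to zero, so any held-out measurement is determined exactly by the
    rest of its pool.  Several pools (rather than one) keep the leave-one-out
    predictions from being a single affine function of the measurements,
    which would make the validation trivially perfect under noise.
    """
    if n_exchanges < 3:
        raise ValueError("need at least 3 exchanges")
    n_pools = max(1, min(n_pools, n_exchanges // 2))
    rng = np.random.default_rng(seed)
    pools = [list(range(p, n_exchanges, n_pools)) for p in range(n_pools)]
    rates = np.zeros(n_exchanges)
    for members in pools:
        vals = rng.uniform(-10.0, 10.0, size=len(members) - 1)
        rates[members[:-1]] = vals
        rates[members[-1]] = -vals.sum()
    mets = [Metabolite(id=f"pool{p}[c]") for p in range(n_pools)]
    rxns: list[Reaction] = []
    flux: dict[str, float] = {}
    for i, f in enumerate(rates):
        pool_id = f"pool{i % n_pools}[c]"
        x = f"x{i}[e]"
        mets.append(Metabolite(id=x))
        rxns.append(
            _mk(f"T{i}", {pool_id: -1.0, x: 1.0}, -bound, bound,
                pathway="transport")
        )
        rxns.append(_mk(f"EX_x{i}", {x: -1.0}, -bound, bound, exchange=True))
        flux[f"T{i}"] = float(f)
        flux[f"EX_x{i}"] = float(f)
    network = MetabolicNetwork(mets, rxns)
    planted = FluxVector(flux, feasible=True)
    assert network.check_flux(planted)
    return SyntheticScenario(
        network=network,
        planted_flux=planted,
        expression_truth={},
        gene_reactions={},
        seed=seed,
        metadata={"generator": "make_conservation_network",
                  "n_exchanges": n_exchanges, "n_pools": n_pools},
    )


def make_random_network(
    seed: int = 0, n_internal: int = 3, reversible_prob: float = 0.5
) -> MetabolicNetwork:
    """A small random loop-free chain network (always feasible: v = 0 works).

    Used for oracle comparisons on networks small enough to enumerate.
    """
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"a{i}[c]") for i in range(n_internal + 1)]
    rxns = [_mk("EX_in", {"a0[c]": -1.0}, -10.0, 0.0, exchange=True)]
    for i in range(n_internal):
        lb = -10.0 if rng.random() < reversible_prob else 0.0
        rxns.append(
            _mk(f"R{i}", {f"a{i}[c]": -1.0, f"a{i + 1}[c]": 1.0}, lb, 10.0)
        )
    if n_internal >= 2 and rng.random() < 0.5:  # parallel shortcut branch
        j = int(rng.integers(0, n_internal - 1))
        rxns.append(
            _mk("RSHORT", {f"a{j}[c]": -1.0, f"a{n_internal}[c]": 1.0},
                0.0, 10.0)
        )
    rxns.append(
        _mk("EX_out", {f"a{n_internal}[c]": -1.0}, 0.0, 10.0, exchange=True)
    )
    return MetabolicNetwork(mets, rxns)


def simulate_measurements(
    scenario: SyntheticScenario,
    sigma: float = 0.0,
    seed: int = 0,
    subset: list[str] | None = None,
) -> FluxMeasurementSet:
    """Noisy exchange measurements f_i = v*_i (1 + e_i), e_i ~ N(0, sigma).

    Multiplicative noise reflects consumption-release measurements whose
    error scales with magnitude.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    exchanges = scenario.network.exchange_reactions()
    if subset is None:
        subset = exchanges
    else:
        bad = sorted(set(subset) - set(exchanges))
        if bad:
            raise ValueError(f"requested non-exchange reactions: {bad}")
    rng = np.random.default_rng(seed)
    out = {}
    for rxn_id in subset:
        v = scenario.planted_flux.rates.get(rxn_id, 0.0)
        out[rxn_id] = v * (1.0 + rng.normal(0.0, sigma)) if sigma > 0 else v
    return FluxMeasurementSet(out)


def simulate_expression(
    scenario: SyntheticScenario,
    miscall_rate: float = 0.0,
    seed: int = 0,
) -> ExpressionProfile:
    """Categorical expression from the truth with seeded miscalls
    (each gene independently flipped to a uniformly chosen other category)."""
    if not 0 <= miscall_rate < 0.5:
        raise ValueError("miscall_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    categories = {}
    for gene in sorted(scenario.expression_truth):
        cat = scenario.expression_truth[gene]
        if miscall_rate > 0 and rng.random() < miscall_rate:
            others = [x for x in CATEGORIES if x != cat]
            cat = others[int(rng.integers(0, len(others)))]
        categories[gene] = cat
    return ExpressionProfile(categories)


#: log-space means of the three expression-level distributions
_VALUE_MU = {LOW: 0.0, MODERATE: 2.0, HIGH: 4.0}


def simulate_expression_values(
    scenario: SyntheticScenario, seed: int = 0, log_sd: float = 0.3
) -> dict[str, float]:
    """Continuous expression values from three shifted log-normals, for
    exercising quantile discretisation end-to-end."""
    rng = np.random.default_rng(seed)
    return {
        gene: float(rng.lognormal(_VALUE_MU[cat], log_sd))
        for gene, cat in sorted(scenario.expression_truth.items())
    }


def make_gene_sets(
    n_universe: int,
    n_up: int,
    n_annotated: int,
    planted_overlap: int,
    seed: int = 0,
) -> tuple[set[str], set[str], set[str]]:
    """Seeded (upregulated, annotated, universe) with an exact overlap."""
    if not (
        0 <= planted_overlap <= min(n_up, n_annotated)
        and max(n_up, n_annotated) <= n_universe
        and n_up + n_annotated - planted_overlap <= n_universe
    ):
        raise ValueError(
            f"inconsistent sizes: N={n_universe}, n_up={n_up}, "
            f"K={n_annotated}, overlap={planted_overlap}"
        )
    rng = np.random.default_rng(seed)
    universe = [f"gene{i:04d}" for i in range(n_universe)]
    order = list(rng.permutation(n_universe))
    shared = [universe[i] for i in order[:planted_overlap]]
    up_only = [
        universe[i] for i in order[planted_overlap : n_up]
    ]
    ann_only = [
        universe[i]
        for i in order[n_up : n_up + n_annotated - planted_overlap]
    ]
    return set(shared + up_only), set(shared + ann_only), set(universe)


def save_scenario(
    scenario: SyntheticScenario,
    outdir: str,
    sigma: float = 0.05,
    miscall_rate: float = 0.0,
    seed: int = 0,
) -> None:
    """Write scenario.json, truth_flux.tsv, expression.tsv, measurements.tsv
    and genesets/ under ``outdir`` (deterministic byte-for-byte)."""
    os.makedirs(outdir, exist_ok=True)
    write_network(scenario.network, os.path.join(outdir, "scenario.json"))
    with open(os.path.join(outdir, "scenario_meta.json"), "w") as fh:
        json.dump(
            {"seed": scenario.seed, "metadata": scenario.metadata},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    with open(os.path.join(outdir, "truth_flux.tsv"), "w") as fh:
        fh.write("reaction_id\trate\n")
        for rid in sorted(scenario.planted_flux.rates):
            fh.write(f"{rid}\t{scenario.planted_flux.rates[rid]!r}\n")
    profile = simulate_expression(scenario, miscall_rate, seed)
    with open(os.path.join(outdir, "expression.tsv"), "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gene in sorted(profile.categories):
            fh.write(f"{gene}\t{profile.categories[gene]}\n")
    measurements = simulate_measurements(scenario, sigma, seed)
    with open(os.path.join(outdir, "measurements.tsv"), "w") as fh:
        fh.write("reaction_id\trate\n")
        for rid in sorted(measurements.measurements):
            fh.write(f"{rid}\t{measurements.measurements[rid]!r}\n")
    up, annotated, universe = make_gene_sets(200, 40, 30, 12, seed)
    gs_dir = os.path.join(outdir, "genesets")
    os.makedirs(gs_dir, exist_ok=True)
    for name, genes in (
        ("upregulated", up), ("oxstress", annotated), ("universe", universe)
    ):
        with open(os.path.join(gs_dir, f"{name}.txt"), "w") as fh:
            for gene in sorted(genes):
                fh.write(gene + "\n")
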