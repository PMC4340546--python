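"""Compartmentalised metabolic network data model and readers/writers.

Conventions
-----------
* Metabolite ids carry their compartment as a bracket suffix (``gsh[c]``,
  ``fum[m]``); the *species key* is the id with the suffix stripped, which is
  what cross-compartment summation (production capacity) groups by.
* Exchange reactions touch exactly one metabolite.  A **positive** flux
  through an exchange denotes secretion and a **negative** flux denotes
  uptake; importers must normalise dialects using the opposite sign.
* Default bounds for otherwise unbounded reactions are ±1000 flux units
  (reversible) and [0, 1000] (irreversible), in arbitrary units
  (conventionally mmol·gDW⁻¹·h⁻¹).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

DEFAULT_BOUND = 1000.0
TOL_BALANCE = 1e-6
TOL_BOUND = 1e-6

_COMPARTMENT_RE = re.compile(r"^(?P<species>.+)\[(?P<comp>[A-Za-z0-9_]+)\]$")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class NetworkFormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


class NetworkValidationError(ValueError):
    """The parsed content violates a data-model invariant."""


def split_compartment(metabolite_id: str) -> tuple[str, str | None]:
    """Return ``(species_key, compartment)`` for a bracket-suffixed id."""
    m = _COMPARTMENT_RE.match(metabolite_id)
    if m:
        return m.group("species"), m.group("comp")
    return metabolite_id, None


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str | None = None
    formula: str | None = None

    def __post_init__(self):
        species, comp = split_compartment(self.id)
        if comp is None and self.compartment is None:
            object.__setattr__(self, "compartment", "c")
        elif comp is not None:
            if self.compartment is not None and self.compartment != comp:
                raise NetworkValidationError(
                    f"metabolite {self.id!r}: declared compartment "
                    f"{self.compartment!r} contradicts id suffix {comp!r}"
                )
            object.__setattr__(self, "compartment", comp)

    @property
    def species_key(self) -> str:
        return split_compartment(self.id)[0]


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    pathway: str = ""
    is_exchange: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class FluxVector:
    """A flux assignment; ``feasible`` asserts steady state within tolerance."""

    rates: dict[str, float]
    feasible: bool = False


class MetabolicNetwork:
    """An ordered collection of metabolites and reactions.

    The induced stoichiometric matrix ``S`` is m × n with metabolites as rows
    (file order) and reactions as columns; negative coefficients denote
    consumption.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        biomass_reaction: str | None = None,
        validate: bool = True,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.biomass_reaction = biomass_reaction
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if validate:
            self.validate()

    # -- structure -----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        data, rows, cols = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                data.append(coef)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
        )

    def species_compartments(self, species_key: str) -> list[str]:
        """Metabolite ids of all compartment instances of a species."""
        return [m.id for m in self.metabolites if m.species_key == species_key]

    def exchange_reactions(self) -> list[str]:
        """Ids of all boundary exchanges (positive flux = secretion)."""
        return [r.id for r in self.reactions if r.is_exchange]

    # -- editing (pure) ------------------------------------------------
    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [replace(m) for m in self.metabolites],
            [replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            self.biomass_reaction,
            validate=False,
        )

    def with_reactions(
        self,
        added: list[Reaction] = (),
        added_metabolites: list[Metabolite] = (),
        removed: list[str] = (),
    ) -> "MetabolicNetwork":
        """Return a new network with reactions added and/or removed."""
        removed = set(removed)
        mets = list(self.metabolites) + list(added_metabolites)
        rxns = [r for r in self.reactions if r.id not in removed] + list(added)
        return MetabolicNetwork(mets, rxns, self.biomass_reaction)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                problems.append(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                problems.append(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if not r.stoichiometry:
                problems.append(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    problems.append(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            if r.is_exchange and len(r.stoichiometry) != 1:
                problems.append(
                    f"exchange reaction {r.id!r} must touch exactly one "
                    f"metabolite, touches {len(r.stoichiometry)}"
                )
        if self.biomass_reaction is not None and self.biomass_reaction not in seen_r:
            problems.append(
                f"biomass reaction {self.biomass_reaction!r} not in network"
            )
        if problems:
            raise NetworkValidationError("; ".join(problems))

    def check_flux(self, flux: FluxVector, tol: float = TOL_BALANCE) -> bool:
        """True iff the flux vector is steady-state and within bounds."""
        v = np.array([flux.rates.get(r.id, 0.0) for r in self.reactions])
        residual = np.abs(self.stoichiometric_matrix() @ v)
        if residual.size and residual.max() > tol:
            return False
        for r, vi in zip(self.reactions, v):
            if vi < r.lower_bound - TOL_BOUND or vi > r.upper_bound + TOL_BOUND:
                return False
        return True

    def mass_imbalances(self) -> dict[str, dict[str, float]]:
        """Elemental imbalance of each non-exchange reaction, where formulas exist.

        Returns reaction id -> {element: net coefficient}; empty dict means
        every checkable reaction balances.  Reactions touching any metabolite
        without a formula are skipped.
        """
        out: dict[str, dict[str, float]] = {}
        for r in self.reactions:
            if r.is_exchange:
                continue
            formulas = [self.metabolite(m).formula for m in r.stoichiometry]
            if any(f is None for f in formulas):
                continue
            net: dict[str, float] = {}
            for met_id, coef in r.stoichiometry.items():
                for elem, count in _parse_formula(self.metabolite(met_id).formula):
                    net[elem] = net.get(elem, 0.0) + coef * count
            net = {e: c for e, c in net.items() if abs(c) > 1e-9}
            if net:
                out[r.id] = net
        return out

    # -- equality ------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.biomass_reaction == other.biomass_reaction
        )


def _parse_formula(formula: str) -> list[tuple[str, int]]:
    return [
        (elem, int(count) if count else 1)
        for elem, count in _FORMULA_RE.findall(formula)
        if elem
    ]


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def network_to_dict(network: MetabolicNetwork) -> dict:
    d = {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula is not None else {}),
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr,
                "pathway": r.pathway,
                "is_exchange": r.is_exchange,
            }
            for r in network.reactions
        ],
    }
    if network.biomass_reaction is not None:
        d["biomass_reaction"] = network.biomass_reaction
    return d


def network_from_dict(d: dict) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment"),
                formula=m.get("formula"),
            )
            for m in d["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lb", -DEFAULT_BOUND)),
                upper_bound=float(r.get("ub", DEFAULT_BOUND)),
                gpr=r.get("gpr", ""),
                pathway=r.get("pathway", ""),
                is_exchange=bool(r.get("is_exchange", False)),
            )
            for r in d["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise NetworkFormatError(f"malformed network document: {exc}") from exc
    return MetabolicNetwork(mets, rxns, d.get("biomass_reaction"))


# TSV equation grammar: "<coef> met[x] + ... -> <coef> met[x] + ..." with
# "->" irreversible and "<->"/"<=>" reversible; a bare "met[x]" has coef 1;
# an empty side denotes the boundary (exchange).
_ARROW_RE = re.compile(r"\s*(<->|<=>|->|=>)\s*")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string; returns (stoichiometry, reversible)."""
    parts = _ARROW_RE.split(equation)
    if len(parts) != 3:
        raise NetworkFormatError(
            f"equation {equation!r}: expected exactly one '->' or '<->'"
        )
    left, arrow, right = parts
    reversible = arrow in ("<->", "<=>")
    stoich: dict[str, float] = {}

    def _side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkFormatError(f"equation {equation!r}: empty term")
            bits = term.split()
            if len(bits) == 1:
                coef, met = 1.0, bits[0]
            elif len(bits) == 2:
                try:
                    coef = float(bits[0])
                except ValueError as exc:
                    raise NetworkFormatError(
                        f"equation {equation!r}: bad coefficient {bits[0]!r}"
                    ) from exc
                met = bits[1]
            else:
                raise NetworkFormatError(
                    f"equation {equation!r}: malformed term {term!r}"
                )
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    _side(left, -1.0)
    _side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise NetworkFormatError(f"equation {equation!r}: no net stoichiometry")
    return stoich, reversible


def format_equation(reaction: Reaction) -> str:
    lhs = [
        f"{-c:g} {m}" for m, c in sorted(reaction.stoichiometry.items()) if c < 0
    ]
    rhs = [f"{c:g} {m}" for m, c in sorted(reaction.stoichiometry.items()) if c > 0]
    arrow = "<->" if reaction.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _load_tsv(path: str) -> MetabolicNetwork:
    import csv

    mets: dict[str, Metabolite] = {}
    rxns: list[Reaction] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "equation"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise NetworkFormatError(
                f"{path}: reactions TSV needs columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                stoich, reversible = parse_equation(row["equation"])
            except NetworkFormatError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: {exc}") from exc
            lb = float(row["lb"]) if row.get("lb") else (
                -DEFAULT_BOUND if reversible else 0.0
            )
            ub = float(row["ub"]) if row.get("ub") else DEFAULT_BOUND
            for met_id in stoich:
                mets.setdefault(met_id, Metabolite(id=met_id))
            rxns.append(
                Reaction(
                    id=row["id"],
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=row.get("gpr", "") or "",
                    pathway=row.get("pathway", "") or "",
                    is_exchange=len(stoich) == 1,
                )
            )
    return MetabolicNetwork(list(mets.values()), rxns)


def _load_sbml(path: str) -> MetabolicNetwork:
    """Read an SBML-FBC model via cobrapy and convert.

    Only the FBC flavour (explicit flux bounds, GPR associations) is
    accepted; cobra raises on anything it cannot interpret, which we
    propagate as a format error.  cobra's exchange sign convention already
    matches ours (negative = uptake).
    """
    try:
        from cobra.io import read_sbml_model
    except ImportError as exc:  # pragma: no cover
        raise NetworkFormatError(
            "SBML import requires the optional 'cobra' dependency"
        ) from exc
    try:
        model = read_sbml_model(path)
    except Exception as exc:
        raise NetworkFormatError(f"{path}: SBML parse failure: {exc}") from exc
    mets = []
    for m in model.metabolites:
        mid = f"{m.id}[{m.compartment}]" if "[" not in m.id else m.id
        mets.append(
            Metabolite(id=mid, name=m.name or "", formula=m.formula or None)
        )
    met_ids = {orig.id: new.id for orig, new in zip(model.metabolites, mets)}
    rxns = []
    exchange_ids = {r.id for r in model.exchanges}
    for r in model.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={
                    met_ids[m.id]: coef for m, coef in r.metabolites.items()
                },
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr=r.gene_reaction_rule or "",
                pathway=r.subsystem or "",
                is_exchange=r.id in exchange_ids or r.boundary,
            )
        )
    biomass = None
    if model.objective is not None:
        obj_rxns = [
            r.id
            for r in model.reactions
            if r.objective_coefficient not in (0, 0.0)
        ]
        if len(obj_rxns) == 1:
            biomass = obj_rxns[0]
    return MetabolicNetwork(mets, rxns, biomass)


def load_network(path: str, format: str = "json") -> MetabolicNetwork:
    """Load a network from ``path`` in the declared dialect.

    Ordering of metabolites and reactions follows the file.
    """
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkFormatError(
                f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}"
            ) from exc
        return network_from_dict(doc)
    if format == "tsv":
        return _load_tsv(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(
    network: MetabolicNetwork, path: str, format: str = "json"
) -> None:
    """Write a network; the output reloads to an equal network and two
    writes of the same network are byte-identical."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(network_to_dict(network), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if format == "tsv":
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "equation", "lb", "ub", "gpr", "pathway"])
            for r in network.reactions:
                writer.writerow(
                    [
                        r.id,
                        format_equation(r),
                        repr(r.lower_bound),
                        repr(r.upper_bound),
                        r.gpr,
                        r.pathway,
                    ]
                )
        return
    raise ValueError(f"unknown network format {format!r}")
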