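"""Tabular readers/writers for the pipeline's TSV/JSON interchange formats."""

from __future__ import annotations

import csv
import json

from .capacity import CapacityTable, CouplingScanResult, FluxRange
from .context import (
    ContextModel,
    ExpressionProfile,
    FluxMeasurementSet,
    ReactionCategories,
)
from .gpr import CATEGORIES
from .network import network_from_dict, network_to_dict
from .validate import LoocvResult


class TableFormatError(ValueError):
    pass


def read_expression_tsv(path: str) -> ExpressionProfile | dict[str, float]:
    """Read expression as (gene_id, value) -> dict of floats, or
    (gene_id, category) -> ExpressionProfile, depending on the header."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        if "gene_id" not in cols or not ({"value", "category"} & set(cols)):
            raise TableFormatError(
                f"{path}: need columns gene_id and value or category"
            )
        categorical = "category" in cols
        values: dict[str, float] = {}
        categories: dict[str, str] = {}
        for lineno, row in enumerate(reader, start=2):
            gene = row["gene_id"]
            if categorical:
                cat = row["category"].strip().upper()
                if cat not in CATEGORIES:
                    raise TableFormatError(
                        f"{path}:{lineno}: unknown category {row['category']!r}"
                    )
                categories[gene] = cat
            else:
                try:
                    values[gene] = float(row["value"])
                except ValueError as exc:
                    raise TableFormatError(
                        f"{path}:{lineno}: bad value {row['value']!r}"
                    ) from exc
    return ExpressionProfile(categories) if categorical else values


def read_measurements_tsv(path: str) -> FluxMeasurementSet:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not {"reaction_id", "rate"} <= set(reader.fieldnames or []):
            raise TableFormatError(
                f"{path}: need columns reaction_id and rate"
            )
        out = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                out[row["reaction_id"]] = float(row["rate"])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}:{lineno}: bad rate {row['rate']!r}"
                ) from exc
    return FluxMeasurementSet(out)


def read_gene_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# -- context model round-trip ----------------------------------------------

def context_to_dict(model: ContextModel) -> dict:
    return {
        "network": network_to_dict(model.network),
        "reaction_categories": dict(sorted(model.reaction_categories.categories.items())),
        "measurements": dict(sorted(model.measurements.measurements.items())),
        "imat_optimum": model.imat_optimum,
        "deviation_optimum": model.deviation_optimum,
        "eps_act": model.eps_act,
        "big_m": model.big_m,
        "lock_rel_tol": model.lock_rel_tol,
        "lock_abs_tol": model.lock_abs_tol,
    }


def context_from_dict(d: dict) -> ContextModel:
    return ContextModel(
        network=network_from_dict(d["network"]),
        reaction_categories=ReactionCategories(d.get("reaction_categories", {})),
        measurements=FluxMeasurementSet(d.get("measurements", {})),
        imat_optimum=int(d.get("imat_optimum", 0)),
        deviation_optimum=float(d.get("deviation_optimum", 0.0)),
        eps_act=float(d.get("eps_act", 1.0)),
        big_m=float(d.get("big_m", 1000.0)),
        lock_rel_tol=float(d.get("lock_rel_tol", 1e-6)),
        lock_abs_tol=float(d.get("lock_abs_tol", 1e-6)),
    )


def save_context(model: ContextModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(context_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_context(path: str) -> ContextModel:
    with open(path) as fh:
        return context_from_dict(json.load(fh))


# -- result tables ----------------------------------------------------------

def write_fva_tsv(ranges: list[FluxRange], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tmin_flux\tmax_flux\tstatus\n")
        for r in ranges:
            fh.write(f"{r.reaction_id}\t{r.min_flux:.9g}\t{r.max_flux:.9g}\t{r.status}\n")


def write_capacity_tsv(table: CapacityTable, path: str) -> None:
    comps = sorted({c for (_, c) in table.per_compartment})
    with open(path, "w") as fh:
        fh.write("species\tcapacity\tflag" + "".join(f"\t{c}" for c in comps) + "\n")
        for species in sorted(table.capacities):
            flag = "infeasible" if species in table.infeasible else ""
            row = [species, f"{table.capacities[species]:.9g}", flag]
            row += [
                f"{table.per_compartment.get((species, c), 0.0):.9g}" for c in comps
            ]
            fh.write("\t".join(row) + "\n")


def write_essentiality_tsv(
    essential: set[str], scanned: list[str], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tessential\n")
        for rid in scanned:
            fh.write(f"{rid}\t{int(rid in essential)}\n")


def write_coupling_tsv(result: CouplingScanResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tcapacity_under_forcing\tflag\n")
        for rid in sorted(result.per_reaction):
            flag = "infeasible" if rid in result.infeasible else ""
            fh.write(f"{rid}\t{result.per_reaction[rid]:.9g}\t{flag}\n")


def write_loocv_tsv(result: LoocvResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "reaction_id\tmeasured\tpred_min\tpred_max\tpred_point\tfold_status\n"
        )
        for f in result.folds:
            fh.write(
                f"{f.held_out_reaction}\t{f.measured:.9g}\t{f.predicted_min:.9g}"
                f"\t{f.predicted_max:.9g}\t{f.point_prediction:.9g}\t{f.status}\n"
            )
        fh.write(
            f"# pearson_r={result.pearson.statistic:.9g}"
            f" p={result.pearson.p_value:.9g} n={result.n}\n"
        )
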