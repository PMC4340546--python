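"""End-to-end pipeline orchestration.

Sequences the analysis stages — context construction, FVA, capacity
analyses (production, redox, pathway fold-changes), succination
perturbation, the GSH dependency sweep, leave-one-out validation and
gene-set enrichment — over file-based inputs, writing one TSV/JSON report
per stage plus a manifest (config hash, seed, package version, stage
statuses) sufficient to reproduce the run.  Reruns with the same config
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import io as cfio
from .capacity import capacity_table, coupling_scan, redox_capacity, run_fva
from .context import ContextModel, build_context, discretize_expression
from .network import load_network
from .perturb import DEFAULT_EPS_SEC, SuccinationSpec, add_succination, dependency_report
from .stats import hypergeometric_enrichment
from .validate import loocv_predict

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_INFEASIBLE = 3
EXIT_SOLVER = 4

STAGES = (
    "build-context",
    "fva",
    "capacity",
    "succinate",
    "sweep",
    "loocv",
    "enrich",
)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    network: str
    expression: str
    measurements: str
    outdir: str
    genesets: dict | None = None  # {"up":, "annotated":, "universe":}
    low_q: float = 0.25
    high_q: float = 0.75
    eps_act: float = 1.0
    big_m: float = 1000.0
    eps_sec: float = DEFAULT_EPS_SEC
    n_points: int = 20
    viability_fraction: float = 0.01
    sweep_target: str = "gsh"
    seed: int = 0
    stages: tuple = STAGES

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad config: {exc}") from exc
        for path_key in ("network", "expression", "measurements"):
            path = getattr(cfg, path_key)
            if not os.path.exists(path):
                raise ConfigError(f"{path_key} path does not exist: {path}")
        if not (0 <= cfg.low_q < cfg.high_q <= 1):
            raise ConfigError("require 0 <= low_q < high_q <= 1")
        if cfg.n_points < 3:
            raise ConfigError("n_points must be >= 3")
        if "loocv" in cfg.stages and not cfg.measurements:
            raise ConfigError("loocv stage enabled but no measurements given")
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> str:
    """Run all configured stages; returns the run directory.

    A stage failure is recorded in the manifest and re-raised after the
    manifest is written, so partial outputs are retained.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": {},
    }
    state: dict = {}
    failure: Exception | None = None
    for stage in cfg.stages:
        t0 = time.monotonic()
        try:
            _run_stage(stage, cfg, state)
            manifest["stages"][stage] = {
                "status": "completed",
                "seconds": round(time.monotonic() - t0, 3),
            }
            logger.info("stage %s completed in %.2fs", stage, time.monotonic() - t0)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            logger.error("stage %s failed: %s", stage, exc)
            failure = exc
            break
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if failure is not None:
        raise failure
    return cfg.outdir


def _versions() -> dict:
    import numpy
    import scipy

    from . import __version__

    return {
        "contextflux": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }


def _run_stage(stage: str, cfg: PipelineConfig, state: dict) -> None:
    out = lambda name: os.path.join(cfg.outdir, name)  # noqa: E731
    if stage == "build-context":
        network = load_network(cfg.network)
        expression = cfio.read_expression_tsv(cfg.expression)
        if isinstance(expression, dict):
            expression = discretize_expression(expression, cfg.low_q, cfg.high_q)
        measurements = cfio.read_measurements_tsv(cfg.measurements)
        ctx = build_context(
            network, expression, measurements,
            cfg.low_q, cfg.high_q, cfg.eps_act, cfg.big_m,
        )
        cfio.save_context(ctx, out("context.json"))
        state["ctx"] = ctx
        state["expression"] = expression
    elif stage == "fva":
        ctx = state["ctx"]
        ranges = run_fva(ctx)
        cfio.write_fva_tsv(ranges, out("fva.tsv"))
    elif stage == "capacity":
        ctx = state["ctx"]
        table = capacity_table(ctx)
        cfio.write_capacity_tsv(table, out("capacity.tsv"))
        state["capacity"] = table
        try:
            nadh, nadph = redox_capacity(ctx)
            redox = {"nadh_capacity": nadh, "nadph_capacity": nadph}
        except ValueError as exc:
            redox = {"error": str(exc)}
        with open(out("redox.json"), "w") as fh:
            json.dump(redox, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif stage == "succinate":
        ctx = state["ctx"]
        spec = SuccinationSpec(sink_min_flux=cfg.eps_sec)
        perturbed_network = add_succination(ctx.network, spec)
        # reconstruct the model on the perturbed network: the grafted
        # reactions change what is attainable, so both optima are re-fit
        # and re-locked rather than inherited
        from .context import fit_fluxes, solve_imat

        _, imat_opt = solve_imat(
            perturbed_network, ctx.reaction_categories, ctx.eps_act, ctx.big_m
        )
        perturbed = fit_fluxes(
            perturbed_network, ctx.reaction_categories, imat_opt,
            ctx.measurements, ctx.eps_act, ctx.big_m,
        )
        state["perturbed"] = perturbed
        table = capacity_table(perturbed)
        cfio.write_capacity_tsv(table, out("capacity_succinated.tsv"))
        report: dict = {"added_reactions": spec.added_reaction_ids}
        try:
            nadh0, nadph0 = redox_capacity(ctx)
            nadh1, nadph1 = redox_capacity(perturbed)
            report |= {
                "nadh_capacity_before": nadh0,
                "nadh_capacity_after": nadh1,
                "nadph_capacity_before": nadph0,
                "nadph_capacity_after": nadph1,
            }
            scan = coupling_scan(
                perturbed, "nadph", reference_reaction="SUCCGSH_SINK"
            )
            report["coupling"] = scan.comparison
            cfio.write_coupling_tsv(scan, out("coupling.tsv"))
        except ValueError as exc:
            report["redox_error"] = str(exc)
        with open(out("succination.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif stage == "sweep":
        model = state.get("perturbed") or state["ctx"]
        df = dependency_report(model, target=cfg.sweep_target, n_points=cfg.n_points)
        df.to_csv(out("dependency.tsv"), sep="\t", index=False, float_format="%.9g")
        for ex, sweep in df.attrs["sweeps"].items():
            with open(out(f"sweep_{ex}.tsv"), "w") as fh:
                fh.write("pinned_flux\tmax_production\n")
                for b, cap in sweep.grid:
                    fh.write(f"{b:.9g}\t{cap:.9g}\n")
    elif stage == "loocv":
        ctx = state["ctx"]
        result = loocv_predict(
            ctx.network, ctx.reaction_categories, ctx.measurements,
            cfg.eps_act, cfg.big_m,
        )
        cfio.write_loocv_tsv(result, out("loocv.tsv"))
    elif stage == "enrich":
        if cfg.genesets is None:
            return
        up = cfio.read_gene_list(cfg.genesets["up"])
        annotated = cfio.read_gene_list(cfg.genesets["annotated"])
        universe = cfio.read_gene_list(cfg.genesets["universe"])
        res = hypergeometric_enrichment(up, annotated, universe)
        with open(out("enrichment.json"), "w") as fh:
            json.dump(
                {
                    "N": res.universe_size,
                    "K": res.annotated_size,
                    "n": res.drawn_size,
                    "k": res.overlap,
                    "p_value": res.p_value,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
    else:
        raise ConfigError(f"unknown stage {stage!r}")
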