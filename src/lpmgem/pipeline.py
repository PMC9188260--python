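"""End-to-end orchestration: fit → bound reduction → loop removal → calls.

Every stage reads and writes plain files, so any intermediate can be
inspected or re-entered, and the composed pipeline equals running the
stage functions by hand with the same inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbon import CarbonCall, call_carbon_sources, correlation_eval, normalized_error, zscore_transporters
from .core import run_fva
from .fit import (
    DiscrepancyReport,
    ExpressionSummary,
    FitConfig,
    ReactionPartition,
    compute_weights,
    solve_fit,
    summarize_expression,
    map_expression_to_flux,
)
from .iffpr import IffprResult, run_iffpr
from .io import read_expression, read_fluxes, read_gpr, read_model, write_fluxes
from .model import FluxSolution, MetabolicNetwork
from .redtil import DEFAULT_THRESHOLD, RedtilResult, run_redtil

__all__ = ["FitInputs", "prepare_fit", "run_pipeline", "PipelineResult"]


@dataclass
class FitInputs:
    """Everything the fit stages need, derived once from the raw inputs."""

    network: MetabolicNetwork
    summary: ExpressionSummary
    partition: ReactionPartition
    fva: pd.DataFrame
    config: FitConfig


def prepare_fit(
    net: MetabolicNetwork,
    expression: pd.DataFrame,
    gpr: dict[str, list[str]],
    core: list[str],
    associated: list[str] | None = None,
    *,
    alpha: float = 0.01,
    exchange_cap: float | None = None,
    designated: list[str] | None = None,
    biomass_floors: dict[str, float] | None = None,
    carbon_uptake: dict[str, float] | None = None,
) -> FitInputs:
    """Run FVA, build the partition, weights and config for the fit."""
    from .core import configure_carbon_uptake_bounds

    if carbon_uptake:
        net = configure_carbon_uptake_bounds(net, carbon_uptake)
    fitted = list(core) + list(associated or [])
    fva = run_fva(net, fitted)
    partition = ReactionPartition.from_sets(net, core, associated, fva)
    summary = summarize_expression(expression, gpr, partition.fitted)
    weights = compute_weights(fva, partition)
    config = FitConfig(
        alpha=alpha,
        weights=weights,
        biomass_floors=dict(biomass_floors or {}),
        exchange_cap=exchange_cap,
        designated=frozenset(designated or []),
    )
    return FitInputs(network=net, summary=summary, partition=partition, fva=fva, config=config)


@dataclass
class PipelineResult:
    inputs: FitInputs
    baseline: tuple[FluxSolution, DiscrepancyReport]
    iffpr: IffprResult | None
    redtil: RedtilResult
    carbon: CarbonCall | None
    metrics: pd.DataFrame | None


def run_pipeline(config: dict, out_dir: str | Path) -> PipelineResult:
    """Execute the full train→reduce→deloop→predict workflow from a config.

    ``config`` is the parsed key-value file; see the README for the schema.
    Writes fluxes, bounds history, cut log, carbon calls, metrics and a run
    manifest into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = read_model(config["model"], config.get("model_format"), biomass=config.get("biomass_reaction"))
    expression = read_expression(config["expression"], config.get("replicate_map"))
    gpr = read_gpr(config["gpr"], net)
    core = _read_list(config["core"])
    associated = _read_list(config["associated"]) if config.get("associated") else []
    biomass_floors = {}
    if config.get("biomass"):
        tbl = pd.read_csv(config["biomass"], sep="\t", index_col=0)
        biomass_floors = tbl.iloc[:, 0].astype(float).to_dict()
    transporters = _read_list(config["transporters"]) if config.get("transporters") else []

    inputs = prepare_fit(
        net,
        expression,
        gpr,
        core,
        associated,
        alpha=float(config.get("alpha", 0.01)),
        exchange_cap=config.get("exchange_cap"),
        designated=config.get("designated", transporters),
        biomass_floors=biomass_floors,
        carbon_uptake=config.get("carbon_uptake"),
    )
    net = inputs.network

    targets = map_expression_to_flux(inputs.summary, inputs.fva)
    baseline = solve_fit(net, targets, inputs.partition, inputs.config)

    iffpr_result = None
    if config.get("iffpr", True):
        iffpr_result = run_iffpr(
            net, inputs.summary, inputs.partition, inputs.config, inputs.fva,
            max_outer=config.get("max_outer"),
        )
        iffpr_result.state.write_history(out / "bounds_history.tsv")
        targets = iffpr_result.targets

    redtil_result = run_redtil(
        net, targets, inputs.partition, inputs.config,
        threshold=float(config.get("til_threshold", DEFAULT_THRESHOLD)),
    )
    redtil_result.log.to_csv(out / "cut_log.tsv", sep="\t", index=False)
    write_fluxes(redtil_result.solution.fluxes, out / "fluxes.tsv")

    carbon = None
    if transporters:
        z, excluded = zscore_transporters(redtil_result.solution, transporters)
        carbon = call_carbon_sources(z, excluded)
        carbon.to_json(out / "carbon_calls.json")

    metrics = None
    if config.get("reference"):
        reference = read_fluxes(config["reference"])
        rows = []
        for cond in reference.columns:
            if cond not in redtil_result.solution.conditions:
                continue
            rows.append(
                {
                    "condition": cond,
                    "normalized_error": normalized_error(
                        redtil_result.solution.fluxes[cond], reference[cond]
                    ),
                }
            )
        metrics = pd.DataFrame(rows)
        r = correlation_eval(redtil_result.solution.fluxes, reference, by="condition")
        metrics["pearson_r"] = r.reindex(metrics["condition"]).to_numpy()
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.get("seed"),
        "versions": {
            "lpmgem": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "discrepancy": {
            "baseline": baseline[1].total,
            "after_iffpr": iffpr_result.final_discrepancy if iffpr_result else None,
            "final": redtil_result.report.total,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        inputs=inputs,
        baseline=baseline,
        iffpr=iffpr_result,
        redtil=redtil_result,
        carbon=carbon,
        metrics=metrics,
    )


def _read_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
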