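"""End-to-end orchestration: generate/load -> select -> diagnose -> effects.

One master seed deterministically derives every stage seed through a
splittable stream, so two runs with the same configuration produce
identical artifacts.  Every stage writes its output as delimited or
JSON text into the run directory; the elbow series and the selection
trace allow the loss-vs-model-size plot to be rebuilt from artifacts
alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from . import schema
from .effects import effect_table, spline_effect_curves
from .forest import ForestParams, fit_forest, oob_quantile_predictions
from .metrics import (
    TAU_GRID,
    TAU_SELECTION,
    average_quantile_loss,
    r1_goodness_of_fit,
)
from .selection import (
    SelectionTrace,
    backward_stepwise,
    relative_importance,
    trace_to_frame,
)
from .synthetic import default_config, generate_episodes

logger = logging.getLogger("qrfcost")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Run-level configuration; exactly one of ``input_path`` / ``generator``."""

    input_path: str | None = None
    generator: dict | None = None
    tau_selection: float = TAU_SELECTION
    tau_grid: tuple[float, ...] = TAU_GRID
    n_trees: int = 1000
    mtry: int | None = None
    min_node_size: int = 10
    importance_mode: str = "pinball"
    seed_policy: str = "common"
    bootstrap_B: int = 1000
    seed: int = 0
    output_dir: str = "qrfcost_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tau_grid" in doc:
            doc["tau_grid"] = tuple(doc["tau_grid"])
        return cls(**doc)

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_path / generator must be configured"
            )


@dataclass
class RunReport:
    """Assembled run outputs; every number traces to a seeded stage."""

    trace: SelectionTrace
    optimal_set: tuple[str, ...]
    relative_importance: pd.DataFrame
    diagnostics: dict
    effects: pd.DataFrame
    age_curves: pd.DataFrame | None
    config: RunConfig
    stage_seeds: dict = field(default_factory=dict)


def _stage_seeds(master: int) -> dict:
    children = np.random.SeedSequence(master).spawn(4)
    names = ("generator", "selection", "diagnostics", "effects")
    return {
        name: int(ss.generate_state(1)[0] % 2**31)
        for name, ss in zip(names, children)
    }


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Execute the full analysis and (optionally) write all artifacts."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "run_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {**dataclasses.asdict(config), "stage_seeds": seeds},
                fh, sort_keys=False, allow_unicode=True,
            )

    # --- data stage
    if config.input_path is not None:
        logger.info("loading episodes from %s", config.input_path)
        table = qio.read_episode_table(config.input_path)
    else:
        gen_kwargs = dict(config.generator or {})
        gen_kwargs.setdefault("seed", seeds["generator"])
        gcfg = default_config(**gen_kwargs)
        logger.info("generating %d episodes (seed %d)", gcfg.n_episodes, gcfg.seed)
        table = generate_episodes(gcfg)
        if write:
            qio.write_episode_table(table, outdir / "episodes.csv")
            qio.write_generator_echo(gcfg, outdir / "generator_config.yaml")
        schema.validate_table(table)

    # --- selection stage
    fp = ForestParams(
        n_trees=config.n_trees,
        mtry=config.mtry,
        min_node_size=config.min_node_size,
        seed=seeds["selection"],
    )
    logger.info(
        "backward stepwise at tau=%.2f (%d trees, %s importance)",
        config.tau_selection, config.n_trees, config.importance_mode,
    )
    trace = backward_stepwise(
        table,
        tau=config.tau_selection,
        forest_params=fp,
        importance_mode=config.importance_mode,
        seed_policy=config.seed_policy,
    )
    optimal = trace.optimal_set
    relimp = relative_importance(trace)
    logger.info("optimal set (%d variables): %s", len(optimal), ", ".join(optimal))

    # --- diagnostics: OOB AQL and R1 of the optimal model
    fp_diag = dataclasses.replace(fp, seed=seeds["diagnostics"])
    forest = fit_forest(table, fp_diag, covariates=list(optimal))
    pred, mask = oob_quantile_predictions(forest, config.tau_selection)
    y = table[schema.RESPONSE].to_numpy(dtype=float)
    diagnostics = {
        "tau": config.tau_selection,
        "oob_aql": average_quantile_loss(y[mask], pred[mask], config.tau_selection),
        "r1": r1_goodness_of_fit(y[mask], pred[mask], config.tau_selection),
        "n_used": int(mask.sum()),
    }
    logger.info("optimal model: OOB AQL %.1f, R1 %.3f", diagnostics["oob_aql"], diagnostics["r1"])

    # --- effect stage
    effects = effect_table(
        table, list(optimal), taus=config.tau_grid,
        B=config.bootstrap_B, seed=seeds["effects"],
    )
    age_curves = None
    if "age" in optimal:
        age_curves = spline_effect_curves(
            table, list(optimal), spline_cov="age", taus=config.tau_grid
        )

    if write:
        trace.to_json(outdir / "selection_trace.json")
        trace_to_frame(trace).to_csv(outdir / "elbow.tsv", sep="\t", index=False)
        relimp.to_csv(outdir / "relative_importance.csv", index=False)
        qio.write_json(diagnostics, outdir / "diagnostics.json")
        effects.to_csv(outdir / "effect_table.csv", index=False)
        if age_curves is not None:
            age_curves.to_csv(outdir / "age_spline_curves.csv", index=False)

    return RunReport(
        trace=trace,
        optimal_set=optimal,
        relative_importance=relimp,
        diagnostics=diagnostics,
        effects=effects,
        age_curves=age_curves,
        config=config,
        stage_seeds=seeds,
    )
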