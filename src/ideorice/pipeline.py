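"""End-to-end orchestration: sensitivity -> target selection -> per-environment
GA -> similarity, with serialized artifacts between stages."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ideorice import __version__
from ideorice.crop_model import (
    DEFAULT_COEFFICIENTS,
    OPTIMIZED_COEFFICIENTS,
    EnvironmentScenario,
    GeneticCoefficients,
)
from ideorice.optimizer import GAConfig, convergence_generation, optimize_environment
from ideorice.sensitivity import (
    ParameterSpace,
    default_space,
    make_simulator,
    replicate_screening,
    select_targets,
)
from ideorice.similarity import CultivarPanel, analyze
from ideorice.synthetic_data import generate_environment_set, generate_panel

logger = logging.getLogger("ideorice")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat, serializable settings for one full run."""

    seed: int = 0
    outdir: str = "ideorice_out"
    # data stage
    panel_path: str | None = None   # CSV; generated synthetically when absent
    panel_size: int = 21
    n_days: int = 170
    # sensitivity stage
    trajectories: int = 10
    replications: int = 20
    min_rsi: float = 0.05
    top_n: int = 8
    # optimizer stage
    generations: int = 40
    pop_size: int = 15
    mutation_prob: float = 0.7
    wue_min: float = 2.0
    wue_max: float = 15.0
    # similarity stage
    top_k: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    config: PipelineConfig
    selected_targets: list[str]
    ga_runs: dict
    ideotypes: CultivarPanel
    report: object
    total_evaluations: int
    manifest: dict


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
            else:
                logger.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def run_pipeline(
    config: PipelineConfig,
    environments: list[EnvironmentScenario] | None = None,
) -> PipelineResult:
    """Execute all three layers and write the report bundle.

    Any stage failure is re-raised as :class:`StageError` tagged with the
    stage name; artifacts written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        "environments": int(rng.integers(2**31)),
        "panel": int(rng.integers(2**31)),
        "sensitivity": int(rng.integers(2**31)),
        "optimizer": int(rng.integers(2**31)),
    }

    try:
        with _timed("data"):
            if environments is None:
                environments = generate_environment_set(
                    seeds["environments"], n_days=config.n_days
                )
            if config.panel_path:
                panel = CultivarPanel.from_csv(config.panel_path)
            else:
                panel = generate_panel(config.panel_size, seed=seeds["panel"])
                panel.to_csv(outdir / "panel.csv")
    except Exception as exc:
        raise StageError("data", exc) from exc

    try:
        with _timed("sensitivity"):
            space11 = default_space()
            simulator = make_simulator(environments[0], names=space11.names)
            matrix = replicate_screening(
                space11,
                simulator,
                r=config.trajectories,
                reps=config.replications,
                seed=seeds["sensitivity"],
            )
            matrix.to_frame().to_csv(outdir / "rsi.csv", index=False)
            targets = select_targets(matrix, top_n=config.top_n, min_rsi=config.min_rsi)
            (outdir / "targets.json").write_text(json.dumps(targets, indent=2))
    except Exception as exc:
        raise StageError("sensitivity", exc) from exc

    try:
        with _timed("optimize"):
            space8 = space11.subset(targets)
            weights = matrix.max_rsi()[[space11.names.index(n) for n in targets]]
            ga_runs = {}
            ideo_rows = []
            total_evals = 0
            for i, env in enumerate(environments):
                ga_config = GAConfig(
                    space=space8,
                    generations=config.generations,
                    pop_size=config.pop_size,
                    mutation_prob=config.mutation_prob,
                    wue_min=config.wue_min,
                    wue_max=config.wue_max,
                    seed=seeds["optimizer"] + i,
                    sensitivity_weights=weights,
                )
                run = optimize_environment(env, ga_config)
                ga_runs[env.label] = run
                total_evals += run.n_evaluations
                run.archive.to_csv(outdir / f"ga_archive_{env.label}.csv", index=False)
                summary = {
                    "environment": env.label,
                    "best": dict(zip(space8.names, run.best_individual.tolist())),
                    "best_fitness": run.best_fitness,
                    "HI": run.best_record.hi,
                    "WUE": run.best_record.wue,
                    "convergence_generation": convergence_generation(run),
                    "seed": ga_config.seed,
                }
                (outdir / f"ga_summary_{env.label}.json").write_text(
                    json.dumps(summary, indent=2)
                )
                ideo_rows.append((f"ID{i + 1}", run))
    except Exception as exc:
        raise StageError("optimize", exc) from exc

    try:
        with _timed("similarity"):
            base = DEFAULT_COEFFICIENTS
            ideo_values = []
            for _, run in ideo_rows:
                coeffs = run.best_coefficients(base)
                ideo_values.append(coeffs.as_array(panel.coefficients))
            ideotypes = CultivarPanel(
                names=[name for name, _ in ideo_rows],
                groups=["ideotype"] * len(ideo_rows),
                values=np.array(ideo_values),
            )
            ideotypes.to_csv(outdir / "ideotypes.csv")
            report = analyze(ideotypes, panel, k=config.top_k)
            report.export(outdir)
    except Exception as exc:
        raise StageError("similarity", exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "selected_targets": targets,
        "total_evaluations": total_evals,
        "environments": [
            {"label": e.label, "weight": e.weight} for e in environments
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config,
        selected_targets=targets,
        ga_runs=ga_runs,
        ideotypes=ideotypes,
        report=report,
        total_evaluations=total_evals,
        manifest=manifest,
    )
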