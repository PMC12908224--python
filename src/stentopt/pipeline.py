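"""End-to-end orchestration: table → fit → screen → optimize → report.

A :class:`PipelineConfig` fixes every choice (design space, response table
source, term policy, desirability ranges, grid resolution, screening
threshold, seed) so a run is fully reproducible; the two shipped configs
``doe1.yaml`` and ``doe2.yaml`` encode the settings that reproduce the
study's printed predictions and optima from the packaged tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .design_space import DOE2_FIXED, RESPONSES, FactorSpace, load_factor_space
from .doe import DOETable, generate_ccd, load_doe_table, load_table4, load_table5
from .optimize import (
    DesirabilityResult,
    SensitivityReport,
    default_spec,
    optimize_designs,
    sensitivity_contributions,
)
from .rsm import (
    FitDiagnostics,
    QuadraticModel,
    eq5_terms,
    fit,
    reduce_model,
    residual_diagnostics,
    screen_union,
)
from .surrogate import default_truth, simulate_responses

logger = logging.getLogger("stentopt.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    space: str = "table1"              # preset name or factor-space file
    table: str = "fixture:table4"      # fixture:table4 | fixture:table5 | surrogate | <csv path>
    terms: str = "auto"                # full | eq5 | auto (per-response screen) | auto-union
    range_mode: str = "predicted"      # desirability anchor mode
    grid: int = 21
    t_crit: float | None = None        # None -> computed from residual df
    seed: int = 0
    out_dir: str | None = None
    fixed: dict[str, float] = field(default_factory=dict)  # factors held constant

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def hash(self) -> str:
        # out_dir is where results land, not part of the analysis identity
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    table: DOETable
    models: dict[str, QuadraticModel]
    diagnostics: dict[str, FitDiagnostics]
    optimum: DesirabilityResult
    sensitivity: SensitivityReport
    manifest: dict


def _resolve_table(config: PipelineConfig, space: FactorSpace) -> DOETable:
    src = config.table
    if src == "fixture:table4":
        return load_table4()
    if src == "fixture:table5":
        return load_table5()
    if src == "surrogate":
        plan = generate_ccd(space)
        truth = default_truth(space) if space.names == ("w", "t", "NS", "LA", "SA") else None
        if truth is None:
            raise StageError("table", "surrogate source currently ships a five-factor truth only")
        designs = plan.designs(**config.fixed)
        return simulate_responses(designs, truth, seed=config.seed)
    path = Path(src)
    if not path.exists():
        raise StageError("table", f"table source {src!r} not found")
    return load_doe_table(path, space)


def _fit_models(
    config: PipelineConfig, table: DOETable
) -> tuple[dict[str, QuadraticModel], dict[str, FitDiagnostics]]:
    models: dict[str, QuadraticModel] = {}
    diags: dict[str, FitDiagnostics] = {}
    if config.terms == "auto-union":
        shared = screen_union(table, t_crit=config.t_crit)
    for m in RESPONSES:
        if config.terms == "auto":
            model, diag = reduce_model(table, m.key, t_crit=config.t_crit)
        elif config.terms == "auto-union":
            model = fit(table, m.key, shared, units="natural")
            diag = residual_diagnostics(model)
        elif config.terms in ("full", "eq5"):
            model = fit(table, m.key, config.terms, units="natural")
            diag = residual_diagnostics(model)
        else:
            raise StageError("fit", f"unknown term policy {config.terms!r}")
        residual_diagnostics(model, diag)
        models[m.key] = model
        diags[m.key] = diag
        logger.info("fitted %s: %d terms, R²=%.4f", m.key, len(model.terms), model.r_squared)
    return models, diags


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and (optionally) write the report bundle."""
    t0 = time.time()
    timings: dict[str, float] = {}

    def clock(stage: str) -> None:
        timings[stage] = round(time.time() - t0, 3)

    try:
        space = load_factor_space(config.space)
    except Exception as exc:
        raise StageError("space", str(exc)) from exc
    try:
        table = _resolve_table(config, space)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("table", str(exc)) from exc
    clock("table")
    try:
        models, diags = _fit_models(config, table)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fit", str(exc)) from exc
    clock("fit")
    try:
        optimum = optimize_designs(
            models, space, range_mode=config.range_mode, grid=config.grid, fixed=config.fixed
        )
    except Exception as exc:
        raise StageError("optimize", str(exc)) from exc
    clock("optimize")
    try:
        sensitivity = sensitivity_contributions(models, space)
    except Exception as exc:
        raise StageError("sensitivity", str(exc)) from exc
    clock("sensitivity")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_runs": table.n_runs,
        "timings_s": timings,
        "outputs": [],
    }
    result = PipelineResult(
        config=config,
        table=table,
        models=models,
        diagnostics=diags,
        optimum=optimum,
        sensitivity=sensitivity,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for key, model in result.models.items():
        p = out / f"model_{key}.json"
        model.to_json(p)
        files.append(p.name)
    opt = result.optimum
    optimum_payload = {
        "design": opt.design.as_dict(),
        "coded": opt.coded.tolist(),
        "composite_desirability": opt.composite_d,
        "per_response_desirability": opt.per_response_d,
        "predicted_responses": opt.predicted,
        "trace": opt.trace,
        "seed": result.config.seed,
    }
    (out / "optimum.json").write_text(json.dumps(optimum_payload, indent=1))
    files.append("optimum.json")
    sens = result.sensitivity.table.copy()
    sens.columns = ["__".join(c) for c in sens.columns]
    sens.to_csv(out / "sensitivity.csv")
    files.append("sensitivity.csv")
    (out / "report.md").write_text(_report_markdown(result))
    files.append("report.md")
    result.manifest["outputs"] = files
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def _report_markdown(result: PipelineResult) -> str:
    lines = ["# Stent design optimization report", ""]
    lines.append(f"- config hash: `{result.config.hash()}` (seed {result.config.seed})")
    lines.append(f"- table: {result.config.table} ({result.table.n_runs} runs)")
    lines.append("")
    lines.append("## Fitted models")
    lines.append("")
    lines.append("| response | terms | R² |")
    lines.append("|---|---|---|")
    for key, model in result.models.items():
        labels = ", ".join(t.label for t in model.terms if t.kind != "intercept")
        lines.append(f"| {key} | {labels} | {model.r_squared:.4f} |")
    opt = result.optimum
    lines.append("")
    lines.append("## Optimum")
    lines.append("")
    lines.append(f"- design: {opt.design.as_dict()}")
    lines.append(f"- composite desirability D = {opt.composite_d:.4f}")
    for key, value in opt.predicted.items():
        lines.append(f"- predicted {key}: {value:.3f} (d = {opt.per_response_d[key]:.3f})")
    if opt.trace.get("flat_axes"):
        lines.append(
            f"- note: D is constant along {opt.trace['flat_axes']}; those coordinates are arbitrary"
        )
    lines.append("")
    lines.append("## Sensitivity contributions [% per response]")
    lines.append("")
    sub = result.sensitivity.table.xs("contribution_pct", axis=1, level=1)
    lines.append(sub.round(2).to_markdown())
    lines.append("")
    return "\n".join(lines)
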