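"""End-to-end pipeline: design -> responses -> screening -> model -> surface
-> optimum (-> validation), with a deterministic JSON-able report.

The report carries full-precision numbers; human-readable rendering rounds
to worksheet precision at the formatting layer only. Identical inputs and
configuration produce byte-identical report JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .design import FactorSpec, FactorialDesign, build_design
from .errors import DoeError, StageError
from .io import (
    read_calibration_csv,
    read_factors_csv,
    read_precision_csv,
    read_run_table,
    responses_from_run_table,
)
from .model import fit_full_model, reduced_r_squared
from .response import ResponseVector
from .screening import ScreeningConfig, effects_table, f_screen, pareto_normalized_squares
from .surface import choose_condition, surface_table
from .validation import (
    coefficient_t_tests,
    detection_limits,
    fit_calibration,
    recovery_regression,
)

__all__ = ["AnalysisConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("stressdoe")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    ``factors``/``runs`` accept in-memory objects or CSV paths. The
    significant-term set used for the reduced R^2 can be given explicitly
    (``significant_terms``) or left to the pooled-error F screen;
    ``active_factors`` are the main-effect factors the optimizer may move
    (default: the main effects among the significant terms).
    """

    label: str = "analysis"
    factors: object = None            # list[FactorSpec] | path to factors.csv
    runs: object = None               # ResponseVector | DataFrame | path to runs.csv
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    significant_terms: tuple[str, ...] | None = None
    active_factors: tuple[str, ...] | None = None
    paper_rounding: bool = False
    target_degradation: float = 10.0
    solve_factor: str | None = None
    grid_factor: str | None = None
    surface_levels: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)
    surface_targets: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    calibration: object = None        # DataFrame | path | None
    precision: object = None          # list[PrecisionLevel] | path | None
    out_dir: object = None

    def __post_init__(self):
        if not 0.0 < float(self.target_degradation) < 100.0:
            raise DoeError("target_degradation must lie in (0, 100)")

    def canonical_dict(self) -> dict:
        return {
            "label": self.label,
            "screening": {
                "pool_size": self.screening.pool_size,
                "alpha": self.screening.alpha,
                "f_critical": self.screening.f_critical,
                "yates_rounding": self.screening.yates_rounding,
                "pareto_sort": self.screening.pareto_sort,
            },
            "significant_terms": list(self.significant_terms or []),
            "active_factors": list(self.active_factors or []),
            "paper_rounding": self.paper_rounding,
            "target_degradation": self.target_degradation,
            "solve_factor": self.solve_factor,
            "grid_factor": self.grid_factor,
            "surface_levels": list(self.surface_levels),
            "surface_targets": list(self.surface_targets),
        }


@dataclass
class RunReport:
    """All numeric blocks of one pipeline run, regenerable from inputs."""

    payload: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.payload, indent=indent, sort_keys=True,
                          default=_json_default)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_factors(config) -> tuple[FactorSpec, ...]:
    if config.factors is None:
        raise StageError("design", "no factors supplied")
    if isinstance(config.factors, (str, Path)):
        return tuple(read_factors_csv(config.factors))
    return tuple(config.factors)


def _load_responses(config, design: FactorialDesign) -> ResponseVector:
    runs = config.runs
    if runs is None:
        raise StageError("responses", "no run data supplied")
    if isinstance(runs, ResponseVector):
        return runs
    if isinstance(runs, (str, Path)):
        runs = read_run_table(runs)
    return responses_from_run_table(runs, design, label=config.label)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except DoeError as exc:
        raise StageError(name, str(exc)) from exc


def run_pipeline(config: AnalysisConfig) -> RunReport:
    """Execute the full workflow and assemble a deterministic report."""
    factors = _stage("design", _load_factors, config)
    design = _stage("design", build_design, factors)
    responses = _stage("responses", _load_responses, config, design)

    table = _stage("screening", effects_table, responses, config.screening)
    pareto = _stage("screening", pareto_normalized_squares, table,
                    config.screening.pareto_sort)

    if config.significant_terms is not None:
        significant = tuple(config.significant_terms)
        log.info("significant set supplied explicitly: %s", significant)
    else:
        significant = tuple(_stage("screening", f_screen, table, config.screening))
        log.info("significant set from F screen: %s", significant)
    log.info("yates_rounding=%s pooled_terms=%s error_ms=%g",
             config.screening.yates_rounding, table.pooled_terms, table.error_ms)

    model = _stage("model", fit_full_model, design, responses)
    r2 = _stage("model", reduced_r_squared, table, significant) if significant else None
    model_used = model.rounded(2) if config.paper_rounding else model

    active = config.active_factors
    if active is None:
        # main effects among the significant terms (labels like "X2")
        active = tuple(t for t in significant if t.count("X") == 1) or None
    solve = config.solve_factor
    if solve is None and active:
        solve = active[-1]

    surface = None
    if solve:
        grid = config.grid_factor
        if grid is None and active and len(active) > 1:
            grid = next(f for f in active if f != solve)
        surface = _stage(
            "surface", surface_table, model_used, solve,
            grid, config.surface_levels, config.surface_targets,
        )

    optimum = None
    if active:
        optimum = _stage(
            "optimize", choose_condition, model_used,
            config.target_degradation, active, None, design,
        )

    validation_block = _stage("validation", _run_validation, config)

    payload = {
        "meta": {
            "tool": "stressdoe",
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(config.canonical_dict(), sort_keys=True).encode()
            ).hexdigest(),
        },
        "config": config.canonical_dict(),
        "design": {
            "factors": [
                {"name": f.name, "low": f.low_actual, "high": f.high_actual,
                 "units": f.units}
                for f in design.factors
            ],
            "runs": design.runs.astype(int).tolist(),
            "term_labels": list(design.term_labels),
        },
        "responses": {"label": responses.label, "values": responses.values.tolist()},
        "yates": {
            "responses_used": table.responses.tolist(),
            "contrasts": table.contrasts.tolist(),
            "effects": dict(zip(table.term_labels, table.effects.tolist())),
            "mean_squares": dict(zip(table.term_labels, table.mean_squares.tolist())),
            "f_values": dict(zip(table.term_labels, table.f_values.tolist())),
            "error_ms": table.error_ms,
            "error_df": table.error_df,
            "pooled_terms": list(table.pooled_terms),
        },
        "pareto": [r.__dict__ for r in pareto],
        "model": {
            "equation": model.equation_text(2),
            "intercept": model.intercept,
            "coefficients": dict(model.coefficients),
            "significant_terms": list(significant),
            "r_squared_reduced": r2,
            "paper_rounding": config.paper_rounding,
        },
        "surface": None if surface is None else {
            "solve_factor": surface.solve_factor,
            "grid_factor": surface.grid_factor,
            "grid_levels": list(surface.grid_levels),
            "targets": list(surface.targets),
            "solutions": surface.solutions.tolist(),
            "in_domain": surface.in_domain.tolist(),
        },
        "optimum": None if optimum is None else {
            "coded_point": list(optimum.coded_point),
            "actual_point": list(optimum.actual_point) if optimum.actual_point else None,
            "units": list(optimum.units) if optimum.units else None,
            "predicted_response_pct": optimum.predicted_response,
            "in_domain": optimum.in_domain,
        },
        "validation": validation_block,
    }
    report = RunReport(payload=payload)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / f"{config.label}_report.json")
    return report


def _run_validation(config: AnalysisConfig):
    block = {}
    if config.calibration is not None:
        cal = config.calibration
        if isinstance(cal, (str, Path)):
            cal = read_calibration_csv(cal)
        curve = fit_calibration(cal)
        tt = coefficient_t_tests(curve)
        dl = None
        if not curve.exact_fit:
            dl = detection_limits(curve.residual_sd, curve.slope)
        block["calibration"] = {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "correlation": curve.correlation,
            "linearity_f": curve.linearity_f,
            "f_critical_linearity": curve.f_critical_linearity,
            "slope_t_vs_zero": tt.slope_t,
            "intercept_t_vs_zero": tt.intercept_t,
            "exact_fit": curve.exact_fit,
            "detection_limit": None if dl is None else dl.dl,
            "quantitation_limit": None if dl is None else dl.ql,
        }
    if config.precision is not None:
        levels = config.precision
        if isinstance(levels, (str, Path)):
            levels = read_precision_csv(levels)
        prec = []
        pairs = []
        for level in levels:
            an = level.anova()
            prec.append({
                "level": level.level_label,
                "nominal_mg": level.nominal_amount,
                "day_means": level.day_means.tolist(),
                "day_sds": level.day_sds.tolist(),
                "day_rsds": level.day_rsds.tolist(),
                "bms": an.bms,
                "wms": an.wms,
                "f_value": an.f_value,
                "recovery_pct": level.recovery_pct,
            })
            pairs += [(level.nominal_amount, v) for v in level.values_matrix.ravel()]
        block["precision"] = prec
        rec = recovery_regression(pairs, on="means")
        block["recovery"] = {
            "slope": rec.slope,
            "intercept": rec.intercept,
            "recovery_pct": {str(k): v for k, v in rec.recovery_pct.items()},
        }
    return block or None
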