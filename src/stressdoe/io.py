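"""CSV / JSON input-output for the documented file schemas.

Schemas (comma-separated, '.' decimal, UTF-8, header mandatory):

* factors.csv      -- name,low,high,units
* design.csv       -- run,<main-effect columns>,<interaction columns>
* runs.csv         -- run,<coded factor columns>,response_pct
                      or run,<coded factor columns>,area_unstressed,area_stressed
* calibration.csv  -- concentration,replicate,peak_area
* precision.csv    -- level,nominal_mg,day,replicate,found_mg
* model.json       -- {label, intercept, coefficients{}, significant_terms[],
                      r_squared_reduced}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import FactorSpec, FactorialDesign, build_design
from .errors import DataError, DesignError, ResponseError
from .model import PolynomialModel
from .response import DegradationRecord, ResponseVector, assemble_responses
from .screening import YatesTable, ParetoRow
from .surface import SurfaceSlice, OptimizedCondition
from .validation import PrecisionLevel

__all__ = [
    "read_factors_csv",
    "read_run_table",
    "responses_from_run_table",
    "read_calibration_csv",
    "read_precision_csv",
    "write_design_csv",
    "write_yates_csv",
    "write_pareto_csv",
    "write_surface_csv",
    "write_model_json",
    "read_model_json",
    "write_optimum_json",
]


def _read_csv(path, required: set[str], numeric: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    for col in numeric & set(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # header is line 1
            raise DataError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {row}"
            )
        df[col] = converted
    return df


def read_factors_csv(path) -> list[FactorSpec]:
    df = _read_csv(path, {"name", "low", "high"}, {"low", "high"})
    specs = []
    for _, row in df.iterrows():
        specs.append(
            FactorSpec(
                name=str(row["name"]),
                low_actual=float(row["low"]),
                high_actual=float(row["high"]),
                units=str(row.get("units", "")) if "units" in df.columns else "",
            )
        )
    return specs


def read_run_table(path) -> pd.DataFrame:
    """Read runs.csv with either a response_pct column or two area columns.

    Every column (coded factor levels included) must be numeric.
    """
    path = Path(path)
    header = pd.read_csv(path, nrows=0)
    df = _read_csv(path, {"run"}, set(header.columns))
    has_resp = "response_pct" in df.columns
    has_areas = {"area_unstressed", "area_stressed"} <= set(df.columns)
    if not has_resp and not has_areas:
        raise DataError(
            f"{path}: need either a 'response_pct' column or both area columns"
        )
    return df


def responses_from_run_table(df: pd.DataFrame, design: FactorialDesign,
                             label: str = "") -> ResponseVector:
    """Align a run table to the design's standard order and build responses.

    Rows may arrive in any order; when coded factor columns are present the
    rows are matched to the design by their sign pattern, otherwise the
    1-based ``run`` column is trusted.
    """
    coded_cols = [c for c in design.factor_labels if c in df.columns]
    records = []
    for _, row in df.iterrows():
        if len(coded_cols) == design.k:
            signs = np.sign([float(row[c]) for c in coded_cols])
            matches = np.nonzero((design.runs == signs).all(axis=1))[0]
            if matches.size != 1:
                raise ResponseError(f"run with coded pattern {signs} not in the design")
            idx = int(matches[0]) + 1
        else:
            idx = int(row["run"])
        if "response_pct" in df.columns and not pd.isna(row.get("response_pct", np.nan)):
            records.append(DegradationRecord(run_index=idx, response_pct=float(row["response_pct"])))
        else:
            records.append(
                DegradationRecord(
                    run_index=idx,
                    area_unstressed=float(row["area_unstressed"]),
                    area_stressed=float(row["area_stressed"]),
                )
            )
    return assemble_responses(records, design, label=label)


def read_calibration_csv(path) -> pd.DataFrame:
    return _read_csv(
        path, {"concentration", "peak_area"}, {"concentration", "replicate", "peak_area"}
    )


def read_precision_csv(path) -> list[PrecisionLevel]:
    df = _read_csv(
        path,
        {"level", "nominal_mg", "day", "replicate", "found_mg"},
        {"nominal_mg", "day", "replicate", "found_mg"},
    )
    levels = []
    for label, grp in df.groupby("level", sort=False):
        pivot = grp.pivot(index="day", columns="replicate", values="found_mg")
        if pivot.isna().any().any():
            raise DataError(f"precision level {label!r} is unbalanced")
        levels.append(
            PrecisionLevel(
                level_label=str(label),
                nominal_amount=float(grp["nominal_mg"].iloc[0]),
                values_matrix=pivot.to_numpy(),
            )
        )
    return levels


def write_design_csv(design: FactorialDesign, path) -> None:
    design.to_frame(include_interactions=True).to_csv(path, index=False)


def write_yates_csv(table: YatesTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_pareto_csv(rows: list[ParetoRow], path) -> None:
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(path, index=False)


def write_surface_csv(sl: SurfaceSlice, path) -> None:
    sl.to_frame().to_csv(path, index=False)


def write_model_json(model: PolynomialModel, path) -> None:
    payload = {
        "label": model.label,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "significant_terms": list(model.significant_terms or []),
        "r_squared_reduced": model.r_squared_reduced,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model_json(path) -> PolynomialModel:
    payload = json.loads(Path(path).read_text())
    return PolynomialModel(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        label=payload.get("label", ""),
        significant_terms=tuple(payload.get("significant_terms") or ()) or None,
        r_squared_reduced=payload.get("r_squared_reduced"),
    )


def write_optimum_json(cond: OptimizedCondition, path) -> None:
    payload = {
        "coded_point": list(cond.coded_point),
        "actual_point": list(cond.actual_point) if cond.actual_point else None,
        "units": list(cond.units) if cond.units else None,
        "predicted_response_pct": cond.predicted_response,
        "in_domain": cond.in_domain,
        "observed_response_pct": cond.observed_response,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
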