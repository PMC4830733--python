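"""ICH Q2 analytical-method validation statistics.

Covers the statistics used to validate a stability-indicating HPLC assay:

* calibration regression (peak area vs concentration) with a linearity
  ANOVA (F = regression MS / residual MS) and Student t-tests of the slope
  and intercept against explicit null values;
* detection and quantitation limits from the response standard deviation
  and slope: DL = 3.3*sigma/S, QL = 10*sigma/S;
* accuracy/recovery summaries (found vs added regression, % recovery);
* intermediate precision by one-way ANOVA with day as the grouping factor,
  F = between-day mean square / within-day mean square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "CalibrationCurve",
    "CoefficientTTests",
    "DetectionLimits",
    "PrecisionLevel",
    "PrecisionAnova",
    "RecoveryResult",
    "fit_calibration",
    "coefficient_t_tests",
    "detection_limits",
    "precision_anova",
    "recovery_regression",
    "assay_content",
]


def _calibration_frame(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.copy()
        if "concentration" not in df or "peak_area" not in df:
            raise DataError("calibration frame needs 'concentration' and 'peak_area' columns")
    else:
        df = pd.DataFrame(list(points), columns=["concentration", "peak_area"])
    df = df[["concentration", "peak_area"]].astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise DataError("calibration data contain non-finite values")
    return df


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares calibration line and its linearity diagnostics.

    ``aggregation`` records whether the regression was run on per-
    concentration mean responses (``"means"``, the default, giving a
    linearity F on (1, m-2) df for m concentration levels) or on every
    replicate (``"raw"``).
    """

    points: pd.DataFrame = field(repr=False)
    slope: float
    intercept: float
    correlation: float
    slope_se: float
    intercept_se: float
    residual_sd: float
    df_resid: int
    linearity_f: float
    f_critical_linearity: float
    aggregation: str
    exact_fit: bool

    @property
    def n_levels(self) -> int:
        return self.points["concentration"].nunique()

    def predict(self, concentration):
        return self.intercept + self.slope * np.asarray(concentration, dtype=float)

    def inverse(self, peak_area):
        if self.slope <= 0:
            raise DataError("cannot invert a curve with non-positive slope")
        return (np.asarray(peak_area, dtype=float) - self.intercept) / self.slope


def fit_calibration(points, aggregate: str = "means", alpha: float = 0.05) -> CalibrationCurve:
    """Fit the calibration line and run the linearity ANOVA.

    With ``aggregate="means"`` replicate areas are averaged per
    concentration before the regression; ``"raw"`` uses every point. An
    exactly collinear data set is reported with ``exact_fit=True`` and an
    infinite linearity F (exceeding any critical value).
    """
    if aggregate not in ("means", "raw"):
        raise DataError(f"unknown aggregation {aggregate!r}")
    df = _calibration_frame(points)
    if df["concentration"].nunique() < 3:
        raise DataError("calibration needs at least 3 distinct concentrations")
    if aggregate == "means":
        fitted = df.groupby("concentration", as_index=False)["peak_area"].mean()
    else:
        fitted = df
    x = fitted["concentration"].to_numpy()
    y = fitted["peak_area"].to_numpy()
    res = stats.linregress(x, y)
    n = x.size
    dof = n - 2
    resid = y - (res.intercept + res.slope * x)
    sse = float(resid @ resid)
    ssr = float(res.slope**2 * np.sum((x - x.mean()) ** 2))
    exact = sse <= 1e-12 * max(1.0, float(y @ y))
    mse = sse / dof if dof > 0 else np.nan
    linearity_f = np.inf if exact or mse == 0 else ssr / mse
    return CalibrationCurve(
        points=df,
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        residual_sd=float(np.sqrt(mse)) if dof > 0 else np.nan,
        df_resid=int(dof),
        linearity_f=float(linearity_f),
        f_critical_linearity=float(stats.f.ppf(1 - alpha, 1, dof)) if dof > 0 else np.nan,
        aggregation=aggregate,
        exact_fit=bool(exact),
    )


@dataclass(frozen=True)
class CoefficientTTests:
    slope_t: float | None
    slope_p: float | None
    intercept_t: float | None
    intercept_p: float | None
    df: int
    exact_fit: bool


def coefficient_t_tests(curve: CalibrationCurve, slope_null: float = 0.0,
                        intercept_null: float = 0.0) -> CoefficientTTests:
    """Student t-tests of slope and intercept against explicit null values.

    t = (estimate - null) / SE on n-2 df. For an exact fit the standard
    errors vanish; the result is flagged rather than reporting infinite t.
    """
    if curve.exact_fit or curve.slope_se == 0 or curve.intercept_se == 0:
        slope_matches = abs(curve.slope - slope_null) < 1e-9 * max(1.0, abs(slope_null))
        int_matches = abs(curve.intercept - intercept_null) < 1e-9 * max(
            1.0, abs(intercept_null)
        )
        return CoefficientTTests(
            slope_t=0.0 if slope_matches else None,
            slope_p=None,
            intercept_t=0.0 if int_matches else None,
            intercept_p=None,
            df=curve.df_resid,
            exact_fit=True,
        )
    st = (curve.slope - slope_null) / curve.slope_se
    it = (curve.intercept - intercept_null) / curve.intercept_se
    return CoefficientTTests(
        slope_t=float(st),
        slope_p=float(2 * stats.t.sf(abs(st), curve.df_resid)),
        intercept_t=float(it),
        intercept_p=float(2 * stats.t.sf(abs(it), curve.df_resid)),
        df=curve.df_resid,
        exact_fit=False,
    )


@dataclass(frozen=True)
class DetectionLimits:
    """ICH Q2 detection and quantitation limits from sigma and slope."""

    response_sd: float
    slope: float
    dl: float
    ql: float


def detection_limits(response_sd: float, slope: float) -> DetectionLimits:
    """DL = 3.3*sigma/S and QL = 10*sigma/S (ICH Q2)."""
    sd, s = float(response_sd), float(slope)
    if s <= 0:
        raise DataError(f"slope must be positive, got {s}")
    if sd < 0:
        raise DataError(f"response SD must be nonnegative, got {sd}")
    return DetectionLimits(response_sd=sd, slope=s, dl=3.3 * sd / s, ql=10.0 * sd / s)


@dataclass(frozen=True)
class PrecisionAnova:
    """One-way (day-grouped) ANOVA decomposition for one accuracy level."""

    bms: float
    wms: float
    f_value: float
    df_between: int
    df_within: int
    degenerate: bool


def precision_anova(values) -> PrecisionAnova:
    """Between-day / within-day ANOVA of a balanced days x replicates table.

    BMS = r * sum_d (mean_d - grand)^2 / (d-1); WMS pools the within-day
    squared deviations on d*(r-1) df; F = BMS/WMS. A table of identical
    values has no variance to partition and is flagged degenerate.
    """
    if hasattr(values, "values_matrix"):
        arr = np.asarray(values.values_matrix, dtype=float)
    else:
        try:
            arr = np.asarray(values, dtype=float)
        except ValueError:
            raise DataError("unbalanced precision table: days have unequal replicate counts") from None
    if arr.ndim != 2:
        raise DataError(f"expected a 2-D days x replicates table, got ndim={arr.ndim}")
    d, r = arr.shape
    if d < 2 or r < 2:
        raise DataError("need at least 2 days and 2 replicates per day")
    grand = arr.mean()
    day_means = arr.mean(axis=1)
    ssb = r * float(np.sum((day_means - grand) ** 2))
    ssw = float(np.sum((arr - day_means[:, None]) ** 2))
    df_b, df_w = d - 1, d * (r - 1)
    bms, wms = ssb / df_b, ssw / df_w
    if wms == 0.0:
        return PrecisionAnova(bms, wms, np.nan if bms == 0 else np.inf,
                              df_b, df_w, degenerate=True)
    return PrecisionAnova(bms, wms, bms / wms, df_b, df_w, degenerate=False)


@dataclass(frozen=True)
class PrecisionLevel:
    """One fortification level of the accuracy/precision study.

    ``values_matrix`` is days x replicates (rows are days), in mg.
    """

    level_label: str
    nominal_amount: float
    values_matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.values_matrix, dtype=float)
        if arr.ndim != 2:
            raise DataError("precision values must form a 2-D days x replicates table")
        arr.setflags(write=False)
        object.__setattr__(self, "values_matrix", arr)

    @property
    def day_means(self) -> np.ndarray:
        return self.values_matrix.mean(axis=1)

    @property
    def day_sds(self) -> np.ndarray:
        return self.values_matrix.std(axis=1, ddof=1)

    @property
    def day_rsds(self) -> np.ndarray:
        return 100.0 * self.day_sds / self.day_means

    @property
    def recovery_pct(self) -> float:
        return 100.0 * float(self.values_matrix.mean()) / self.nominal_amount

    def anova(self) -> PrecisionAnova:
        return precision_anova(self.values_matrix)


@dataclass(frozen=True)
class RecoveryResult:
    """Found-vs-added regression and per-level % recovery."""

    pairs: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    recovery_pct: dict[float, float]


def recovery_regression(pairs, on: str = "means") -> RecoveryResult:
    """Least squares of amount found on amount added.

    ``on="means"`` regresses the per-level mean found values on the added
    amounts (one point per level); ``"raw"`` uses every pair. Per-level
    recovery is 100 * mean(found) / added.
    """
    if on not in ("means", "raw"):
        raise DataError(f"unknown regression mode {on!r}")
    pts = [(float(a), float(f)) for a, f in pairs]
    if not pts:
        raise DataError("no recovery pairs supplied")
    df = pd.DataFrame(pts, columns=["added", "found"])
    if df["added"].nunique() < 2:
        raise DataError("recovery regression needs at least 2 distinct added amounts")
    means = df.groupby("added", as_index=False)["found"].mean()
    reg_df = means if on == "means" else df
    res = stats.linregress(reg_df["added"], reg_df["found"])
    recovery = {
        float(a): float(100.0 * f / a) for a, f in zip(means["added"], means["found"])
    }
    return RecoveryResult(
        pairs=tuple(pts),
        slope=float(res.slope),
        intercept=float(res.intercept),
        recovery_pct=recovery,
    )


def assay_content(sample_area, curve: CalibrationCurve, nominal_conc: float):
    """Drug content as % of label claim from a sample peak area.

    The area is referred to the calibration line and the recovered
    concentration expressed relative to the nominal (label-claim)
    concentration. Accepts a scalar or an array of replicate areas.
    """
    nominal = float(nominal_conc)
    if nominal <= 0:
        raise DataError("nominal concentration must be positive")
    conc = curve.inverse(sample_area)
    out = 100.0 * conc / nominal
    return float(out) if np.isscalar(sample_area) else out
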