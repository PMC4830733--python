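"""Synthetic data generators mirroring the statistical structure of the
forced-degradation study inputs.

Three generators cover everything the pipeline consumes:

* factorial responses: a known multilinear polynomial in coded units plus
  i.i.d. Gaussian noise (optionally back-converted to stressed peak areas
  against a fixed unstressed reference);
* calibration points: a straight line with additive Gaussian noise,
  replicated per concentration;
* precision tables: a day random effect plus within-day replicate noise,
  value_{d,r} = nominal + day_d + eps_{d,r}.

All generators draw from a single ``numpy.random.default_rng`` stream seeded
explicitly, so output is bit-reproducible per seed, and they carry their
spec alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import FactorialDesign, build_design, FactorSpec
from .errors import DataError
from .response import ResponseVector
from .screening import ScreeningConfig, effects_table, f_screen
from .model import PolynomialModel

__all__ = [
    "SyntheticFactorialSpec",
    "SyntheticCalibrationSpec",
    "SyntheticPrecisionSpec",
    "gen_factorial_responses",
    "gen_calibration_data",
    "gen_precision_table",
    "screening_power_report",
    "default_acid_scenario",
]


@dataclass(frozen=True)
class SyntheticFactorialSpec:
    """Ground truth for factorial-response generation.

    ``coefficients`` maps term labels to true coded-unit coefficients (%);
    ``noise_sd`` is the i.i.d. Gaussian response noise in % degradation.
    """

    design: FactorialDesign
    intercept: float
    coefficients: dict[str, float]
    noise_sd: float = 0.5
    replicate_runs: int = 1
    seed: int = 0
    unstressed_area: float = 1_000_000.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DataError("noise_sd must be nonnegative")
        if self.replicate_runs < 1:
            raise DataError("replicate_runs must be >= 1")
        unknown = [t for t in self.coefficients if t not in self.design.term_labels]
        if unknown:
            raise DataError(f"coefficient terms {unknown} not in the design")

    def truth_model(self) -> PolynomialModel:
        coefs = {t: float(self.coefficients.get(t, 0.0)) for t in self.design.term_labels}
        return PolynomialModel(
            intercept=float(self.intercept), coefficients=coefs, design=self.design,
            label="synthetic-truth",
        )

    def mean_responses(self) -> np.ndarray:
        m = self.design.model_matrix()
        beta = np.array(
            [self.intercept]
            + [self.coefficients.get(t, 0.0) for t in self.design.term_labels]
        )
        return m @ beta


def gen_factorial_responses(spec: SyntheticFactorialSpec, with_areas: bool = False):
    """Draw factorial responses Y_i = polynomial(run_i) + eps_i.

    Returns a single :class:`ResponseVector` when ``replicate_runs == 1``,
    otherwise a list of independent replicate vectors. With
    ``with_areas=True`` also returns a run table of stressed/unstressed peak
    areas consistent with the responses.
    """
    rng = np.random.default_rng(spec.seed)
    mu = spec.mean_responses()
    n = mu.size
    reps = []
    for r in range(spec.replicate_runs):
        y = mu + rng.normal(0.0, spec.noise_sd, size=n)
        reps.append(ResponseVector(values=y, label=f"synthetic[{spec.seed}]"))
    out = reps[0] if spec.replicate_runs == 1 else reps
    if not with_areas:
        return out
    y0 = reps[0].values
    areas = pd.DataFrame(
        {
            "run": np.arange(1, n + 1),
            "area_unstressed": np.full(n, spec.unstressed_area),
            "area_stressed": spec.unstressed_area * (1.0 - y0 / 100.0),
        }
    )
    return out, areas


@dataclass(frozen=True)
class SyntheticCalibrationSpec:
    """Ground truth for calibration-line generation (area = a*conc + b + eps)."""

    true_slope: float
    true_intercept: float
    concentrations: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DataError("noise_sd must be nonnegative")


def gen_calibration_data(spec: SyntheticCalibrationSpec) -> pd.DataFrame:
    """Replicate calibration points as a (concentration, replicate, peak_area) frame."""
    if spec.replicates < 1:
        raise DataError("replicates must be >= 1")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in spec.concentrations:
        for r in range(1, spec.replicates + 1):
            area = spec.true_intercept + spec.true_slope * c + rng.normal(0.0, spec.noise_sd)
            rows.append((float(c), r, float(area)))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "peak_area"])


@dataclass(frozen=True)
class SyntheticPrecisionSpec:
    """Ground truth for day-nested precision tables.

    value_{d,r} = nominal + day_d + eps_{d,r}, day_d ~ N(0, between^2),
    eps ~ N(0, within^2).
    """

    nominal: float
    between_day_sd: float
    within_day_sd: float
    days: int = 3
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.between_day_sd < 0 or self.within_day_sd < 0:
            raise DataError("variance components must be nonnegative")
        if self.days < 2 or self.replicates < 2:
            raise DataError("need at least 2 days and 2 replicates")


def gen_precision_table(spec: SyntheticPrecisionSpec, label: str = "synthetic"):
    """Generate a balanced days x replicates table as a PrecisionLevel."""
    from .validation import PrecisionLevel

    rng = np.random.default_rng(spec.seed)
    day_effects = rng.normal(0.0, spec.between_day_sd, size=spec.days)
    noise = rng.normal(0.0, spec.within_day_sd, size=(spec.days, spec.replicates))
    values = spec.nominal + day_effects[:, None] + noise
    return PrecisionLevel(level_label=label, nominal_amount=spec.nominal,
                          values_matrix=values)


def screening_power_report(spec: SyntheticFactorialSpec,
                           config: ScreeningConfig | None = None,
                           n_sims: int = 500) -> dict[str, float]:
    """Per-term detection frequency of the pooled-error F screen.

    Simulates ``n_sims`` response sets from the spec (seeds derived from
    ``spec.seed``) and reports, for every design term, the fraction of
    simulations in which it passed :func:`f_screen`.
    """
    if n_sims < 1:
        raise DataError("n_sims must be >= 1")
    config = config or ScreeningConfig()
    mu = spec.mean_responses()
    rng = np.random.default_rng(spec.seed)
    counts = {t: 0 for t in spec.design.term_labels}
    for _ in range(n_sims):
        y = mu + rng.normal(0.0, spec.noise_sd, size=mu.size)
        table = effects_table(ResponseVector(values=y), config)
        for t in f_screen(table, config):
            counts[t] += 1
    return {t: c / n_sims for t, c in counts.items()}


def default_acid_scenario(seed: int = 0, noise_sd: float = 0.5) -> SyntheticFactorialSpec:
    """Default synthetic scenario: the acid-degradation system's magnitudes.

    Truth coefficients mirror the fitted acid polynomial (intercept ~18.32%,
    dominant temperature and heating-time effects) with 0.5% response noise,
    so simulated data look like a realistic 2^3 forced-degradation study.
    """
    factors = (
        FactorSpec("acid_strength", 0.01, 0.1, "mol/L"),
        FactorSpec("temperature", 55.0, 80.0, "degC"),
        FactorSpec("heating_time", 30.0, 60.0, "min"),
    )
    design = build_design(factors)
    coefficients = {
        "X1": -0.67, "X2": 10.26, "X3": 4.56,
        "X1X2": -0.16, "X2X3": 2.59, "X1X3": 0.44, "X1X2X3": -0.10,
    }
    return SyntheticFactorialSpec(
        design=design, intercept=18.32, coefficients=coefficients,
        noise_sd=noise_sd, seed=seed,
    )
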