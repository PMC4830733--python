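"""Two-level full factorial designs in coded units.

A 2^k full factorial design runs every combination of k factors, each at a
coded low (-1) and high (+1) level. Runs are kept in *standard (Yates) order*
-- the first listed factor alternates fastest -- because the Yates algorithm
in :mod:`stressdoe.screening` requires that ordering. Effect columns
(including all interaction products) are mutually orthogonal, which is what
makes the contrast-based coefficient formulas exact least squares.

Coded and actual units are linked by the affine map

    coded = (actual - midpoint) / half_range

so the low level maps to -1 and the high level to +1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError, ExtrapolationWarning

__all__ = [
    "FactorSpec",
    "FactorialDesign",
    "build_design",
    "code_value",
    "decode_value",
    "yates_term_labels",
    "term_factor_indices",
]

MAX_FACTORS = 12  # 2^12 = 4096 runs; guard against exponential blowup

_TERM_RE = re.compile(r"X(\d+)")


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its actual low/high levels.

    Parameters
    ----------
    name:
        Label of the factor (e.g. ``"X1"`` or ``"acid strength"``).
    low_actual, high_actual:
        Actual values assigned to the coded -1 and +1 levels, in ``units``.
    units:
        Physical units of the actual levels (e.g. ``"mol/L"``, ``"degC"``).
    """

    name: str
    low_actual: float
    high_actual: float
    units: str = ""

    def __post_init__(self):
        if not self.name or not str(self.name).strip():
            raise DesignError("factor name must be a nonempty string")
        lo, hi = float(self.low_actual), float(self.high_actual)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise DesignError(f"factor {self.name!r}: levels must be finite")
        if not hi > lo:
            raise DesignError(
                f"factor {self.name!r}: high level ({hi}) must exceed low level ({lo})"
            )

    @property
    def midpoint(self) -> float:
        return (float(self.low_actual) + float(self.high_actual)) / 2.0

    @property
    def half_range(self) -> float:
        return (float(self.high_actual) - float(self.low_actual)) / 2.0


def code_value(actual: float, spec: FactorSpec) -> float:
    """Transform an actual factor value to coded units.

    Values outside the [-1, +1] experimental domain are returned as-is but
    raise an :class:`ExtrapolationWarning`, since conclusions of a two-level
    design are only supported inside the domain.
    """
    coded = (float(actual) - spec.midpoint) / spec.half_range
    if abs(coded) > 1.0 + 1e-12:
        warnings.warn(
            f"coded value {coded:.4g} for factor {spec.name!r} lies outside [-1, +1]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return coded


def decode_value(coded: float, spec: FactorSpec) -> float:
    """Transform a coded value back to actual units (inverse of code_value)."""
    coded = float(coded)
    if abs(coded) > 1.0 + 1e-12:
        warnings.warn(
            f"decoding coded value {coded:.4g} outside [-1, +1] for factor {spec.name!r}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return spec.midpoint + coded * spec.half_range


def yates_term_labels(k: int) -> tuple[str, ...]:
    """Effect-term labels for a 2^k design in standard Yates (binary) order.

    Term ``i`` (1-based) involves factor ``j`` iff bit ``j`` of ``i`` is set,
    so for k=3: X1, X2, X1X2, X3, X1X3, X2X3, X1X2X3. This is exactly the
    order in which the Yates algorithm emits contrasts.
    """
    labels = []
    for idx in range(1, 2**k):
        facs = [j for j in range(k) if (idx >> j) & 1]
        labels.append("".join(f"X{j + 1}" for j in facs))
    return tuple(labels)


def term_factor_indices(label: str) -> tuple[int, ...]:
    """Zero-based factor indices appearing in a term label like ``"X1X3"``."""
    idx = tuple(int(m) - 1 for m in _TERM_RE.findall(label))
    if not idx:
        raise DesignError(f"cannot parse term label {label!r}")
    return idx


@dataclass(frozen=True)
class FactorialDesign:
    """A 2^k full factorial design in standard Yates order.

    ``runs`` is the (2^k, k) matrix of coded main-effect levels; interaction
    columns are derived on demand as elementwise products.
    """

    factors: tuple[FactorSpec, ...]
    runs: np.ndarray = field(repr=False)
    term_labels: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def factor_labels(self) -> tuple[str, ...]:
        return tuple(f"X{i + 1}" for i in range(self.k))

    def effect_column(self, label: str) -> np.ndarray:
        """Coded column for any main-effect or interaction term."""
        idx = term_factor_indices(label)
        if any(i >= self.k for i in idx):
            raise DesignError(f"term {label!r} references a factor beyond k={self.k}")
        return np.prod(self.runs[:, idx], axis=1)

    def model_matrix(self) -> np.ndarray:
        """(2^k, 2^k) matrix: all-ones column followed by every effect column."""
        cols = [np.ones(self.n_runs)]
        cols += [self.effect_column(lab) for lab in self.term_labels]
        return np.column_stack(cols)

    def run_sign_labels(self) -> tuple[str, ...]:
        """Human-readable sign tuples, e.g. ``"(-,+,-)"``, one per run."""
        return tuple(
            "(" + ",".join("+" if v > 0 else "-" for v in row) + ")"
            for row in self.runs
        )

    def code_point(self, actual_point) -> np.ndarray:
        return np.array(
            [code_value(a, f) for a, f in zip(actual_point, self.factors, strict=True)]
        )

    def decode_point(self, coded_point) -> np.ndarray:
        return np.array(
            [decode_value(c, f) for c, f in zip(coded_point, self.factors, strict=True)]
        )

    def to_frame(self, include_interactions: bool = True):
        """Design as a DataFrame with a 1-based ``run`` column, signs as ints."""
        import pandas as pd

        data = {"run": np.arange(1, self.n_runs + 1)}
        labels = self.term_labels if include_interactions else self.factor_labels
        for lab in labels:
            data[lab] = self.effect_column(lab).astype(int)
        return pd.DataFrame(data)


def build_design(factors) -> FactorialDesign:
    """Build the 2^k full factorial design for the given factors.

    Runs are generated in standard Yates order: run ``i`` (0-based) has
    factor ``j`` at the high level iff bit ``j`` of ``i`` is set, so the
    first factor alternates fastest.
    """
    factors = tuple(factors)
    k = len(factors)
    if k == 0:
        raise DesignError("a design needs at least one factor")
    if k > MAX_FACTORS:
        raise DesignError(f"k={k} exceeds the supported maximum of {MAX_FACTORS}")
    names = [f.name for f in factors]
    if len(set(names)) != k:
        raise DesignError(f"duplicate factor names: {sorted(names)}")
    n = 2**k
    runs = np.empty((n, k))
    for j in range(k):
        runs[:, j] = np.where((np.arange(n) >> j) & 1, 1.0, -1.0)
    runs.setflags(write=False)
    return FactorialDesign(factors=factors, runs=runs, term_labels=yates_term_labels(k))
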