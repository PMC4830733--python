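"""% degradation responses from stressed vs unstressed peak areas.

The response of a forced-degradation run is the relative loss of the drug
peak area against a single unstressed comparator at the same nominal
concentration:

    % degradation = 100 * (area_unstressed - area_stressed) / area_unstressed
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import FactorialDesign
from .errors import NegativeDegradationWarning, ResponseError

__all__ = [
    "DegradationRecord",
    "ResponseVector",
    "percent_degradation",
    "assemble_responses",
]


def percent_degradation(area_unstressed: float, area_stressed: float) -> float:
    """Percent loss of drug peak area relative to the unstressed reference.

    Scale-invariant: multiplying both areas by the same positive constant
    leaves the result unchanged. A stressed area larger than the reference
    yields a negative value and a :class:`NegativeDegradationWarning`.
    """
    u, s = float(area_unstressed), float(area_stressed)
    if not u > 0:
        raise ResponseError(f"unstressed area must be positive, got {u}")
    if s < 0:
        raise ResponseError(f"stressed area must be nonnegative, got {s}")
    if s > u:
        warnings.warn(
            f"stressed area ({s}) exceeds unstressed reference ({u}); "
            "negative % degradation",
            NegativeDegradationWarning,
            stacklevel=2,
        )
    return 100.0 * (u - s) / u


@dataclass
class DegradationRecord:
    """One run's degradation measurement.

    Provide either the stressed/unstressed peak areas or a direct
    ``response_pct``; supplying both is accepted only if they agree.
    """

    run_index: int
    area_unstressed: float | None = None
    area_stressed: float | None = None
    response_pct: float | None = None

    def resolve(self) -> float:
        """Return the % degradation this record represents."""
        has_areas = self.area_unstressed is not None or self.area_stressed is not None
        if has_areas and (self.area_unstressed is None or self.area_stressed is None):
            raise ResponseError(
                f"run {self.run_index}: both areas are required when areas are given"
            )
        if has_areas:
            computed = percent_degradation(self.area_unstressed, self.area_stressed)
            if self.response_pct is not None and not np.isclose(
                computed, float(self.response_pct), rtol=1e-6, atol=1e-9
            ):
                raise ResponseError(
                    f"run {self.run_index}: ambiguous record -- areas give "
                    f"{computed:.6g}% but response_pct={self.response_pct}"
                )
            return computed
        if self.response_pct is None:
            raise ResponseError(
                f"run {self.run_index}: record carries neither areas nor response_pct"
            )
        return float(self.response_pct)


@dataclass(frozen=True)
class ResponseVector:
    """Ordered % degradation responses aligned to a design's run order."""

    values: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ResponseError("response vector must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ResponseError("response vector contains non-finite values")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.shape[0]


def assemble_responses(records, design: FactorialDesign, label: str = "") -> ResponseVector:
    """Assemble per-run records into a ResponseVector in standard run order.

    Exactly one record per design run is required; ``run_index`` is 1-based.
    The input order of records does not matter.
    """
    n = design.n_runs
    slots: list[float | None] = [None] * n
    for rec in records:
        i = int(rec.run_index)
        if not 1 <= i <= n:
            raise ResponseError(f"run index {i} outside 1..{n}")
        if slots[i - 1] is not None:
            raise ResponseError(f"duplicate record for run {i}")
        slots[i - 1] = rec.resolve()
    missing = [i + 1 for i, v in enumerate(slots) if v is None]
    if missing:
        raise ResponseError(f"missing records for runs {missing}")
    return ResponseVector(values=np.array(slots, dtype=float), label=label)
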