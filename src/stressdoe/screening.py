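"""Yates-algorithm effect estimation, pooled-error F screening, Pareto ranking.

For a 2^k response vector in standard run order, the Yates algorithm applies
k passes of a pairwise operator (first half: sums of consecutive pairs;
second half: second-minus-first differences). The final column contains the
grand total followed by all 2^k - 1 factorial contrasts in standard term
order. From the contrast c of a term,

    effect      E  = c / 2^(k-1)
    mean square MS = c^2 / 2^k     (1 df each)

In an unreplicated (saturated) design there is no residual to estimate error
from, so the smallest ``pool_size`` mean squares are pooled as the error
estimate (``error_ms``, with ``pool_size`` df) and every effect is tested by
F = MS / error_ms against F(1, pool_size) at the chosen alpha.

The Pareto ranking normalizes the squared effects to percentages,
100 * E^2 / sum(E^2), and sorts rows by decreasing effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import yates_term_labels
from .errors import ScreeningError
from .response import ResponseVector

__all__ = [
    "ScreeningConfig",
    "YatesTable",
    "ParetoRow",
    "yates_transform",
    "effects_table",
    "f_screen",
    "pareto_normalized_squares",
    "round_half_away_from_zero",
]


def round_half_away_from_zero(values) -> np.ndarray:
    """Round to nearest integer with ties going away from zero (7.5 -> 8, -7.5 -> -8)."""
    v = np.asarray(values, dtype=float)
    return np.copysign(np.floor(np.abs(v) + 0.5), v)


@dataclass(frozen=True)
class ScreeningConfig:
    """Configuration for Yates screening.

    pool_size
        Number of smallest effect mean squares pooled as the error estimate.
    alpha
        Significance level used to derive the critical F(1, pool_size) when
        ``f_critical`` is not given explicitly.
    f_critical
        Explicit critical F value; overrides ``alpha`` when set.
    yates_rounding
        ``"none"`` (default) analyzes responses as given;
        ``"nearest-integer"`` rounds them half-away-from-zero first, the
        convention used in hand-computed Yates worksheets.
    pareto_sort
        ``"signed"`` sorts Pareto rows by decreasing signed effect (the
        worksheet convention); ``"abs"`` by decreasing magnitude.
    """

    pool_size: int = 2
    alpha: float = 0.01
    f_critical: float | None = None
    yates_rounding: str = "none"
    pareto_sort: str = "signed"

    def __post_init__(self):
        if self.pool_size < 1:
            raise ScreeningError("pool_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ScreeningError("alpha must be in (0, 1)")
        if self.f_critical is not None and not self.f_critical > 0:
            raise ScreeningError("f_critical must be positive")
        if self.yates_rounding not in ("none", "nearest-integer"):
            raise ScreeningError(f"unknown yates_rounding {self.yates_rounding!r}")
        if self.pareto_sort not in ("signed", "abs"):
            raise ScreeningError(f"unknown pareto_sort {self.pareto_sort!r}")

    def resolve_f_critical(self, error_df: int) -> float:
        if self.f_critical is not None:
            return float(self.f_critical)
        return float(stats.f.ppf(1.0 - self.alpha, 1, error_df))


def _as_values(responses) -> np.ndarray:
    if isinstance(responses, ResponseVector):
        return np.asarray(responses.values, dtype=float)
    return np.asarray(responses, dtype=float)


def _yates_stages(y: np.ndarray) -> np.ndarray:
    """All k intermediate Yates columns; the last column holds the contrasts."""
    n = y.shape[0]
    if n < 2 or n & (n - 1):
        raise ScreeningError(f"response length {n} is not a power of two >= 2")
    k = n.bit_length() - 1
    stages = np.empty((n, k))
    cur = y
    for p in range(k):
        pairs = cur.reshape(-1, 2)
        cur = np.concatenate([pairs.sum(axis=1), pairs[:, 1] - pairs[:, 0]])
        stages[:, p] = cur
    return stages


def yates_transform(responses) -> np.ndarray:
    """Factorial contrasts of a standard-order 2^k response vector.

    Returns the final Yates column: element 0 is the grand total, elements
    1..2^k-1 are the effect contrasts in standard term order. Equivalent to
    the dot product of each effect column with the responses.
    """
    return _yates_stages(_as_values(responses))[:, -1]


@dataclass(frozen=True)
class YatesTable:
    """Full Yates worksheet for one response set.

    Arrays ``effects``, ``mean_squares`` and ``f_values`` are aligned to
    ``term_labels`` (length 2^k - 1, standard term order); the intercept/base
    row carries the grand total only.
    """

    label: str
    responses: np.ndarray = field(repr=False)
    stages: np.ndarray = field(repr=False)
    contrasts: np.ndarray = field(repr=False)
    term_labels: tuple[str, ...]
    effects: np.ndarray = field(repr=False)
    mean_squares: np.ndarray = field(repr=False)
    error_ms: float
    error_df: int
    pooled_terms: tuple[str, ...]
    f_values: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return len(self.responses).bit_length() - 1

    @property
    def n_runs(self) -> int:
        return self.responses.shape[0]

    def _index(self, term: str) -> int:
        try:
            return self.term_labels.index(term)
        except ValueError:
            raise ScreeningError(f"unknown term {term!r}") from None

    def effect(self, term: str) -> float:
        return float(self.effects[self._index(term)])

    def mean_square(self, term: str) -> float:
        return float(self.mean_squares[self._index(term)])

    def f_value(self, term: str) -> float:
        return float(self.f_values[self._index(term)])

    def to_frame(self):
        """Worksheet as a DataFrame: response, stage columns, effect, MS, F.

        The first (base) row shows the grand total in the contrast column and
        blanks for effect/MS/F, mirroring hand-worksheet layout.
        """
        import pandas as pd

        n, k = self.n_runs, self.k
        data = {"term": ("(1)",) + self.term_labels, "response": self.responses}
        for p in range(k):
            data[chr(ord("A") + p)] = self.stages[:, p]
        data["effect"] = np.concatenate([[np.nan], self.effects])
        data["mean_square"] = np.concatenate([[np.nan], self.mean_squares])
        data["f_value"] = np.concatenate([[np.nan], self.f_values])
        data["pooled"] = [False] + [t in self.pooled_terms for t in self.term_labels]
        return pd.DataFrame(data)


def effects_table(responses, config: ScreeningConfig | None = None,
                  label: str | None = None) -> YatesTable:
    """Run the Yates algorithm and build the effect/MS/F worksheet.

    The error mean square is the mean of the ``config.pool_size`` smallest
    non-intercept mean squares (ties broken by term order); every effect --
    pooled ones included, annotated via ``pooled_terms`` -- receives an
    F value against it.
    """
    config = config or ScreeningConfig()
    y = _as_values(responses)
    if label is None:
        label = responses.label if isinstance(responses, ResponseVector) else ""
    if config.yates_rounding == "nearest-integer":
        y = round_half_away_from_zero(y)
    stages = _yates_stages(y)
    contrasts = stages[:, -1]
    n = y.shape[0]
    k = n.bit_length() - 1
    n_effects = n - 1
    if config.pool_size >= n_effects:
        raise ScreeningError(
            f"pool_size={config.pool_size} must be smaller than the "
            f"{n_effects} available effects"
        )
    effects = contrasts[1:] / 2 ** (k - 1)
    mean_squares = contrasts[1:] ** 2 / n
    order = np.argsort(mean_squares, kind="stable")
    pooled_idx = order[: config.pool_size]
    error_ms = float(mean_squares[pooled_idx].mean())
    labels = yates_term_labels(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_values = np.where(
            mean_squares > 0,
            np.divide(mean_squares, error_ms) if error_ms > 0 else np.inf,
            0.0,
        )
    return YatesTable(
        label=label,
        responses=y,
        stages=stages,
        contrasts=contrasts,
        term_labels=labels,
        effects=effects,
        mean_squares=mean_squares,
        error_ms=error_ms,
        error_df=int(config.pool_size),
        pooled_terms=tuple(labels[i] for i in sorted(pooled_idx)),
        f_values=f_values,
    )


def f_screen(table: YatesTable, config: ScreeningConfig | None = None,
             candidates=None) -> list[str]:
    """Terms whose F value exceeds the critical F, in design term order.

    ``candidates`` restricts the terms under consideration (e.g. to main
    effects only, a common practice in screening write-ups); default is all
    effect terms.
    """
    config = config or ScreeningConfig()
    f_crit = config.resolve_f_critical(table.error_df)
    if candidates is None:
        candidates = table.term_labels
    else:
        unknown = [t for t in candidates if t not in table.term_labels]
        if unknown:
            raise ScreeningError(f"unknown candidate terms {unknown}")
    return [t for t in table.term_labels if t in set(candidates) and table.f_value(t) > f_crit]


@dataclass(frozen=True)
class ParetoRow:
    rank: int
    effect_label: str
    effect_value: float
    effect_squared: float
    normalized_square: float


def pareto_normalized_squares(table: YatesTable, sort: str | None = None) -> list[ParetoRow]:
    """Pareto ranking of effects by normalized squares (percent of sum E^2).

    The intercept/base row is excluded; normalized squares over all ranked
    effects sum to 100.
    """
    sort = sort or "signed"
    if sort not in ("signed", "abs"):
        raise ScreeningError(f"unknown pareto sort {sort!r}")
    e = table.effects
    total = float(np.sum(e**2))
    if total <= 0:
        raise ScreeningError("all effects are zero; normalized squares undefined")
    key = -e if sort == "signed" else -np.abs(e)
    order = np.argsort(key, kind="stable")
    rows = []
    for rank, i in enumerate(order, start=1):
        rows.append(
            ParetoRow(
                rank=rank,
                effect_label=table.term_labels[i],
                effect_value=float(e[i]),
                effect_squared=float(e[i] ** 2),
                normalized_square=float(100.0 * e[i] ** 2 / total),
            )
        )
    return rows
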