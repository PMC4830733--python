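"""Response-surface inversion and target-condition selection.

The fitted 2^k polynomial is multilinear, so with all factors but one held
fixed it is *linear* in the remaining factor: Y = a + b x. Solving for the
factor at a target response is therefore exact,

    x = (target - a) / b,

where ``a`` collects the intercept and all terms not containing the solved
factor (evaluated at the fixed values) and ``b`` the coefficients of terms
containing it. Surface slices tabulate such solutions over a grid of another
factor and several targets; solutions outside [-1, +1] are reported and
marked out-of-domain rather than clipped, since the model is only supported
inside the experimental domain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import FactorialDesign, term_factor_indices
from .errors import DomainError, SolveError
from .model import PolynomialModel

__all__ = [
    "SurfaceSlice",
    "OptimizedCondition",
    "ComparisonSummary",
    "invert_single_factor",
    "surface_table",
    "choose_condition",
    "compare_predicted_observed",
]

_SUBSTITUTION_TOL = 1e-6


def _factor_label(i: int) -> str:
    return f"X{i + 1}"


def _linearize(model: PolynomialModel, solve_idx: int, fixed: dict[int, float]):
    """Constant and slope of the model in the solved factor at fixed values."""
    a = model.intercept
    b = 0.0
    for term, coef in model.coefficients.items():
        idx = term_factor_indices(term)
        others = [i for i in idx if i != solve_idx]
        try:
            prod = float(np.prod([fixed[i] for i in others])) if others else 1.0
        except KeyError as exc:
            raise SolveError(
                f"factor X{exc.args[0] + 1} appears in term {term!r} but has no fixed value"
            ) from None
        if solve_idx in idx:
            b += coef * prod
        else:
            a += coef * prod
    return a, b


def _parse_fixed(model: PolynomialModel, solve_factor: str, fixed) -> dict[int, float]:
    k = model.n_factors
    solve_idx = term_factor_indices(solve_factor)
    if len(solve_idx) != 1:
        raise SolveError(f"solve factor must be a single main effect, got {solve_factor!r}")
    (solve_idx,) = solve_idx
    fixed = dict(fixed or {})
    fixed_idx: dict[int, float] = {}
    for key, val in fixed.items():
        (i,) = term_factor_indices(key) if isinstance(key, str) else (int(key),)
        fixed_idx[i] = float(val)
    missing = [
        _factor_label(i) for i in range(k) if i != solve_idx and i not in fixed_idx
    ]
    if missing:
        raise SolveError(f"factors {missing} must be fixed to solve for {solve_factor}")
    return solve_idx, fixed_idx


def invert_single_factor(model: PolynomialModel, target: float, solve_factor: str,
                         fixed) -> float:
    """Coded value of one factor achieving ``target`` %, others fixed.

    Exact because the polynomial is linear in a single factor; raises
    :class:`SolveError` when the effective slope vanishes.
    """
    solve_idx, fixed_idx = _parse_fixed(model, solve_factor, fixed)
    a, b = _linearize(model, solve_idx, fixed_idx)
    if abs(b) < 1e-12:
        raise SolveError(
            f"model is flat in {solve_factor} at the given fixed values; no solution"
        )
    return (float(target) - a) / b


@dataclass(frozen=True)
class SurfaceSlice:
    """Solved factor values over a grid of one factor and several targets.

    ``solutions[i, j]`` solves the model for ``solve_factor`` at grid level
    ``grid_levels[i]`` and target ``targets[j]``; ``in_domain`` marks
    |solution| <= 1. Every solution is substitution-checked on construction.
    """

    solve_factor: str
    grid_factor: str | None
    fixed_values: dict[str, float]
    grid_levels: tuple[float, ...]
    targets: tuple[float, ...]
    solutions: np.ndarray = field(repr=False)
    in_domain: np.ndarray = field(repr=False)

    def to_frame(self):
        import pandas as pd

        col = self.grid_factor if self.grid_factor else "level"
        frame = pd.DataFrame(
            self.solutions, columns=[f"{t:g}%" for t in self.targets]
        )
        frame.insert(0, col, self.grid_levels if self.grid_factor else [np.nan] * len(self.grid_levels))
        return frame


def surface_table(model: PolynomialModel, solve_factor: str,
                  grid_factor: str | None = None, grid_levels=(),
                  targets=(), fixed=None) -> SurfaceSlice:
    """Tabulate inversions of ``solve_factor`` over grid levels x targets.

    Factors other than the solved and grid factors default to coded 0.
    With ``grid_factor=None`` a single row is produced at the fixed values.
    """
    k = model.n_factors
    fixed = {str(key): float(v) for key, v in (fixed or {}).items()}
    base = {_factor_label(i): 0.0 for i in range(k)}
    base.update(fixed)
    base.pop(solve_factor, None)
    if grid_factor is None:
        grid_levels = (0.0,)
    else:
        grid_levels = tuple(float(g) for g in grid_levels)
    targets = tuple(float(t) for t in targets)
    sols = np.full((len(grid_levels), len(targets)), np.nan)
    for i, g in enumerate(grid_levels):
        point_fixed = dict(base)
        if grid_factor is not None:
            point_fixed[grid_factor] = g
        for j, t in enumerate(targets):
            x = invert_single_factor(model, t, solve_factor, point_fixed)
            # substitution check: the solved point must reproduce the target
            point = _assemble_point(model, solve_factor, x, point_fixed)
            back = _predict_quiet(model, point)
            if abs(back - t) > _SUBSTITUTION_TOL * max(1.0, abs(t)):
                raise SolveError(
                    f"substitution check failed at grid={g}, target={t}: {back} != {t}"
                )
            sols[i, j] = x
    return SurfaceSlice(
        solve_factor=solve_factor,
        grid_factor=grid_factor,
        fixed_values={key: v for key, v in base.items() if grid_factor is None or key != grid_factor},
        grid_levels=grid_levels,
        targets=targets,
        solutions=sols,
        in_domain=np.abs(sols) <= 1.0 + 1e-9,
    )


def _assemble_point(model, solve_factor, x, fixed) -> np.ndarray:
    k = model.n_factors
    point = np.zeros(k)
    for key, v in fixed.items():
        (i,) = term_factor_indices(key)
        point[i] = v
    (si,) = term_factor_indices(solve_factor)
    point[si] = x
    return point


def _predict_quiet(model, point) -> float:
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return model.predict(point)


@dataclass(frozen=True)
class OptimizedCondition:
    """A coded point achieving a target response, with its decoded conditions."""

    coded_point: tuple[float, ...]
    actual_point: tuple[float, ...] | None
    units: tuple[str, ...] | None
    predicted_response: float
    in_domain: bool
    observed_response: float | None = None


def choose_condition(model: PolynomialModel, target: float,
                     active_factors=None, fixed=None,
                     design: FactorialDesign | None = None) -> OptimizedCondition:
    """Choose an in-domain coded point whose predicted response equals target.

    Inactive factors are held at coded 0 (or at values given in ``fixed``).
    Strategy: first try all active factors at 0; otherwise enumerate, for
    each active factor in turn, every +/-1 bound assignment of the remaining
    active factors and solve the last factor exactly. Among feasible points
    the one with smallest max-norm wins, ties broken lexicographically.
    Raises :class:`DomainError` when the target is unattainable in
    [-1, +1]^k, reporting the attainable range.
    """
    k = model.n_factors
    target = float(target)
    design = design if design is not None else model.design
    if active_factors is None:
        if model.significant_terms:
            active = [t for t in model.significant_terms if len(term_factor_indices(t)) == 1]
        else:
            active = [_factor_label(i) for i in range(k)]
    else:
        active = list(active_factors)
    if not active:
        raise SolveError("no active factors to optimize over")
    fixed = {str(key): float(v) for key, v in (fixed or {}).items()}
    base = {_factor_label(i): 0.0 for i in range(k)}
    base.update(fixed)

    # attainable range over the closed domain: multilinear => extrema at corners
    corners = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    preds = [_predict_quiet(model, c) for c in corners]
    lo, hi = min(preds), max(preds)
    if not lo - 1e-9 <= target <= hi + 1e-9:
        raise DomainError(
            f"target {target}% outside the attainable range "
            f"[{lo:.4g}, {hi:.4g}] over the coded domain"
        )

    candidates: list[np.ndarray] = []
    # all-active-at-zero candidate (covers target == centre prediction)
    centre = dict(base)
    centre_point = np.array([centre[_factor_label(i)] for i in range(k)])
    if abs(_predict_quiet(model, centre_point) - target) <= 1e-9 * max(1.0, abs(target)):
        candidates.append(centre_point)
    for solve in active:
        others = [f for f in active if f != solve]
        for bounds in itertools.product([-1.0, 1.0], repeat=len(others)):
            point_fixed = dict(base)
            point_fixed.update(dict(zip(others, bounds)))
            point_fixed.pop(solve, None)
            try:
                x = invert_single_factor(model, target, solve, point_fixed)
            except SolveError:
                continue
            if abs(x) > 1.0 + 1e-9:
                continue
            candidates.append(
                _assemble_point(model, solve, float(np.clip(x, -1.0, 1.0)), point_fixed)
            )
    if not candidates:
        raise DomainError(
            f"no in-domain solution found for target {target}% with active factors {active}"
        )
    best = min(candidates, key=lambda p: (round(np.abs(p).max(), 12), tuple(p)))
    predicted = _predict_quiet(model, best)
    actual = units = None
    if design is not None:
        actual = tuple(float(v) for v in design.decode_point(best))
        units = tuple(f.units for f in design.factors)
    return OptimizedCondition(
        coded_point=tuple(float(v) for v in best),
        actual_point=actual,
        units=units,
        predicted_response=predicted,
        in_domain=bool(np.all(np.abs(best) <= 1.0 + 1e-9)),
    )


@dataclass(frozen=True)
class ComparisonSummary:
    """Confirmation-run comparison of observed responses to the prediction."""

    predicted: float
    mean_observed: float
    difference: float
    n: int
    t_statistic: float | None
    p_value: float | None
    exact_agreement: bool


def compare_predicted_observed(condition: OptimizedCondition, observed) -> ComparisonSummary:
    """One-sample t-test of confirmation runs against the predicted response.

    With fewer than two replicates, or zero spread exactly at the predicted
    value, no t-statistic is computed and the comparison is reported by the
    difference alone.
    """
    obs = np.asarray(list(observed), dtype=float)
    if obs.size == 0:
        raise SolveError("at least one observed confirmation value is required")
    predicted = float(condition.predicted_response)
    mean = float(obs.mean())
    diff = mean - predicted
    if obs.size < 2:
        return ComparisonSummary(predicted, mean, diff, int(obs.size), None, None,
                                 abs(diff) < 1e-12)
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        return ComparisonSummary(predicted, mean, diff, int(obs.size),
                                 None if diff == 0 else float("inf"),
                                 None, diff == 0.0)
    t = diff / (sd / np.sqrt(obs.size))
    p = 2.0 * stats.t.sf(abs(t), obs.size - 1)
    return ComparisonSummary(predicted, mean, diff, int(obs.size), float(t), float(p), False)
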