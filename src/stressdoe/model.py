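"""Saturated coded-unit polynomial models for 2^k factorial responses.

The model for a 2^k design is multilinear in the coded factors:

    Y = b0 + sum_j b_j X_j + sum_{i<j} b_ij X_i X_j + ... + b_1..k X_1...X_k

Because the effect columns are orthogonal, the least-squares coefficients
have closed forms: b0 = sum(Y)/2^k and b_term = (column . Y)/2^k, i.e. half
the Yates effect. The saturated model has as many coefficients as runs and
interpolates the observations exactly.

A reduced-model fit quality is summarized as the fraction of effect mean
squares carried by the retained (significant) terms:

    R^2 = sum(MS significant) / sum(MS all effects)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .design import FactorialDesign, term_factor_indices
from .errors import ExtrapolationWarning, ModelError
from .response import ResponseVector
from .screening import YatesTable

__all__ = [
    "PolynomialModel",
    "fit_full_model",
    "predict_response",
    "reduced_r_squared",
]


@dataclass(frozen=True)
class PolynomialModel:
    """Intercept plus coded-unit coefficients keyed by term label."""

    intercept: float
    coefficients: dict[str, float]
    label: str = ""
    significant_terms: tuple[str, ...] | None = None
    r_squared_reduced: float | None = None
    design: FactorialDesign | None = field(default=None, repr=False, compare=False)

    @property
    def n_factors(self) -> int:
        if self.design is not None:
            return self.design.k
        return max(
            (i + 1 for t in self.coefficients for i in term_factor_indices(t)),
            default=0,
        )

    def predict(self, coded_point) -> float:
        """Evaluate the polynomial at a coded point (length = n_factors)."""
        p = np.asarray(coded_point, dtype=float)
        if p.shape != (self.n_factors,):
            raise ModelError(
                f"expected a point of {self.n_factors} coded coordinates, got shape {p.shape}"
            )
        if np.any(np.abs(p) > 1.0 + 1e-12):
            warnings.warn(
                "predicting outside the [-1, +1]^k experimental domain",
                ExtrapolationWarning,
                stacklevel=2,
            )
        y = self.intercept
        for term, coef in self.coefficients.items():
            y += coef * np.prod(p[list(term_factor_indices(term))])
        return float(y)

    def rounded(self, ndigits: int = 2) -> "PolynomialModel":
        """Copy with intercept and coefficients rounded to ``ndigits``.

        Used for report rendering and for reproducing worksheet arithmetic
        that was carried out on rounded equations.
        """
        return replace(
            self,
            intercept=round(self.intercept, ndigits),
            coefficients={t: round(c, ndigits) for t, c in self.coefficients.items()},
        )

    def equation_text(self, ndigits: int = 2) -> str:
        """Render ``Y = b0 + b1X1 - ...`` with coefficients to ``ndigits``.

        Terms appear as main effects first, then interactions by order.
        """
        def sort_key(t):
            idx = term_factor_indices(t)
            return (len(idx), idx)

        parts = [f"Y = {self.intercept:.{ndigits}f}"]
        for term in sorted(self.coefficients, key=sort_key):
            c = self.coefficients[term]
            sign = "-" if c < 0 else "+"
            parts.append(f"{sign} {abs(c):.{ndigits}f}{term}")
        return " ".join(parts)


def fit_full_model(design: FactorialDesign, responses) -> PolynomialModel:
    """Fit the saturated polynomial by the orthogonal contrast formulas.

    Equivalent to ordinary least squares on the full model matrix; the
    fitted model reproduces every observation exactly.
    """
    y = (
        np.asarray(responses.values, dtype=float)
        if isinstance(responses, ResponseVector)
        else np.asarray(responses, dtype=float)
    )
    if y.shape != (design.n_runs,):
        raise ModelError(
            f"responses of length {y.shape} do not match the {design.n_runs}-run design"
        )
    n = design.n_runs
    intercept = float(y.sum() / n)
    coefficients = {
        lab: float(design.effect_column(lab) @ y / n) for lab in design.term_labels
    }
    label = responses.label if isinstance(responses, ResponseVector) else ""
    return PolynomialModel(
        intercept=intercept, coefficients=coefficients, label=label, design=design
    )


def predict_response(model: PolynomialModel, coded_point) -> float:
    """Functional alias of :meth:`PolynomialModel.predict`."""
    return model.predict(coded_point)


def reduced_r_squared(table: YatesTable, significant_terms) -> float:
    """Share of effect mean squares explained by the retained terms.

    R^2 = sum MS(significant) / sum MS(all effects); equals the usual
    coefficient of determination of the reduced model because each effect
    mean square is that term's contribution to the corrected sum of squares.
    """
    significant = list(significant_terms)
    if not significant:
        raise ModelError("significant term set must be nonempty")
    unknown = [t for t in significant if t not in table.term_labels]
    if unknown:
        raise ModelError(f"terms {unknown} not present in the Yates table")
    total = float(table.mean_squares.sum())
    if total <= 0:
        raise ModelError("total effect mean square is zero; R^2 undefined")
    kept = sum(table.mean_square(t) for t in significant)
    return float(kept / total)
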