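"""Built-in chlorthalidone forced-degradation study data.

The published study tables for the worked chlorthalidone case: factor
levels, the 2^3 run responses for acid and alkali stress, and the three-day
accuracy/precision study. Everything downstream (screening, modelling,
optimization, validation) can be exercised directly against these.
"""

from __future__ import annotations

import numpy as np

from .design import FactorSpec, FactorialDesign, build_design
from .response import ResponseVector
from .validation import PrecisionLevel

__all__ = [
    "ACID_FACTORS",
    "ALKALI_FACTORS",
    "ACID_PCT_DEGRADATION",
    "ALKALI_PCT_DEGRADATION",
    "ALKALI_YATES_INPUT",
    "RECOVERY_ADDED_MG",
    "acid_design",
    "alkali_design",
    "acid_responses",
    "alkali_responses",
    "precision_levels",
    "recovery_pairs",
]

# Acid stress: strength of HCl, reflux temperature, heating time.
ACID_FACTORS = (
    FactorSpec("acid_strength", 0.01, 0.1, "mol/L HCl"),
    FactorSpec("temperature", 55.0, 80.0, "degC"),
    FactorSpec("heating_time", 30.0, 60.0, "min"),
)

# Alkali stress: NaOH strength, reflux temperature, shorter heating times.
ALKALI_FACTORS = (
    FactorSpec("alkali_strength", 0.01, 0.1, "mol/L NaOH"),
    FactorSpec("temperature", 55.0, 80.0, "degC"),
    FactorSpec("heating_time", 15.0, 30.0, "min"),
)

# % degradation per run, standard Yates order (first factor fastest).
ACID_PCT_DEGRADATION = (7.14, 5.03, 22.61, 20.27, 10.00, 10.07, 36.23, 35.24)
ALKALI_PCT_DEGRADATION = (5.43, 7.66, 25.43, 27.69, 11.69, 10.25, 32.51, 36.42)

# Integer responses as used in the published alkali Yates worksheet. Note
# run 7 appears there as 32 although 32.51 rounds to 33; the worksheet is
# kept verbatim so its downstream F values can be reproduced exactly.
ALKALI_YATES_INPUT = (5, 8, 25, 28, 12, 10, 32, 36)

# Fortified amounts (mg) for the 80/100/120% accuracy levels.
RECOVERY_ADDED_MG = (10.0, 12.5, 15.0)

# Amount found (mg), rows = days, columns = replicates.
_PRECISION_VALUES = {
    "80% (10 mg)": (
        10.0,
        ((10.00, 10.05, 10.03), (10.02, 10.03, 10.03), (10.00, 10.09, 10.04)),
    ),
    "100% (12.5 mg)": (
        12.5,
        ((12.45, 12.42, 12.33), (12.42, 12.41, 12.49), (12.45, 12.42, 12.46)),
    ),
    "120% (15 mg)": (
        15.0,
        ((14.09, 14.02, 14.06), (14.01, 14.03, 14.04), (14.032, 14.07, 14.09)),
    ),
}


def acid_design() -> FactorialDesign:
    """2^3 design of the acid forced-degradation study."""
    return build_design(ACID_FACTORS)


def alkali_design() -> FactorialDesign:
    """2^3 design of the alkali forced-degradation study."""
    return build_design(ALKALI_FACTORS)


def acid_responses() -> ResponseVector:
    """% acid degradation per run, standard order."""
    return ResponseVector(values=np.array(ACID_PCT_DEGRADATION), label="acid")


def alkali_responses() -> ResponseVector:
    """% alkali degradation per run, standard order."""
    return ResponseVector(values=np.array(ALKALI_PCT_DEGRADATION), label="alkali")


def precision_levels() -> tuple[PrecisionLevel, ...]:
    """Three-day triplicate accuracy/precision study at 80/100/120% levels."""
    return tuple(
        PrecisionLevel(
            level_label=label,
            nominal_amount=nominal,
            values_matrix=np.array(values),
        )
        for label, (nominal, values) in _PRECISION_VALUES.items()
    )


def recovery_pairs() -> list[tuple[float, float]]:
    """(amount added, amount found) for every replicate of every level."""
    pairs = []
    for level in precision_levels():
        for found in level.values_matrix.ravel():
            pairs.append((level.nominal_amount, float(found)))
    return pairs
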