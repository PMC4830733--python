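"""Exception and warning types shared across the package."""


class DoeError(Exception):
    """Base class for all stressdoe errors."""


class DesignError(DoeError):
    """Invalid factor specification or factorial design."""


class ResponseError(DoeError):
    """Invalid, misaligned, or ambiguous degradation-response data."""


class ScreeningError(DoeError):
    """Invalid Yates / pooling / Pareto configuration or degenerate input."""


class ModelError(DoeError):
    """Invalid polynomial-model operation."""


class SolveError(DoeError):
    """Response-surface inversion has no solution (zero effective slope)."""


class DomainError(SolveError):
    """Requested target response is unattainable inside the coded domain."""


class DataError(DoeError):
    """Invalid method-validation input (calibration/precision/recovery)."""


class StageError(DoeError):
    """Pipeline stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class ExtrapolationWarning(UserWarning):
    """Coded value outside the [-1, +1] experimental domain."""


class NegativeDegradationWarning(UserWarning):
    """Stressed peak area exceeds the unstressed reference area."""
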