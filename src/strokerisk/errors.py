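"""Exception hierarchy shared across the package."""


class StrokeRiskError(Exception):
    """Base class for all package errors."""


class ProfileError(StrokeRiskError, ValueError):
    """A risk-factor profile violates its invariants."""


class ConfigError(StrokeRiskError, ValueError):
    """A coefficient set, delta table or threshold file is invalid."""


class CovariateError(StrokeRiskError, KeyError):
    """A model coefficient references a covariate that cannot be derived."""

    def __str__(self) -> str:  # KeyError quotes its message; we do not want that
        return self.args[0] if self.args else ""


class ScoringError(StrokeRiskError, ValueError):
    """Cohort scoring failed (empty input, invalid rows in fail-fast mode, ...)."""


class DataError(StrokeRiskError, ValueError):
    """Malformed input data (CSV schema violation, degenerate outcome vector, ...)."""
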