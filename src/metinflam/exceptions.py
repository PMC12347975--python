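"""Exception hierarchy for metinflam.

Validation failures (bad inputs, bad configs) and degenerate-data outcomes
are kept distinct so the CLI can map them to different exit codes.
"""


class MetinflamError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MetinflamError, ValueError):
    """Invalid user input: bad lab values, malformed config, unknown names."""


class InvalidLabValueError(ValidationError):
    """A laboratory field violates its domain (negative count, zero lymphocytes...)."""

    def __init__(self, field: str, value, reason: str):
        self.field = field
        self.value = value
        super().__init__(f"invalid value for {field!r}: {value!r} ({reason})")


class ConfigError(ValidationError):
    """A cohort or pipeline configuration is internally inconsistent."""


class DegenerateDataError(MetinflamError):
    """The data admit no meaningful statistic (constant samples, empty class...)."""


class SingularMatrixError(MetinflamError):
    """A correlation matrix is numerically rank-deficient."""

    def __init__(self, variables, message: str | None = None):
        self.variables = list(variables)
        super().__init__(
            message
            or "correlation matrix is singular; collinear variables: "
            + ", ".join(self.variables)
        )


class NoAdequateModelError(MetinflamError):
    """Every candidate factor model fell at or below the KMO adequacy threshold."""
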