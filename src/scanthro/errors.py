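"""Exception hierarchy shared across the package."""


class ScanthroError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ScanthroError, ValueError):
    """An input is outside the physically meaningful domain (e.g. height <= 0)."""


class SchemaError(ScanthroError, ValueError):
    """A table or config does not match the expected schema (columns, units)."""


class ConfigError(ScanthroError, ValueError):
    """A generator or pipeline configuration is internally inconsistent."""


class UsageError(ScanthroError, ValueError):
    """An operation was called with arguments that make no sense together."""


class SingularDesignError(ScanthroError, ValueError):
    """A design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"design matrix is singular; collinear columns: {self.columns}"
        )


class EmptyStratumError(ScanthroError, ValueError):
    """A requested stratum contains no participants."""
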