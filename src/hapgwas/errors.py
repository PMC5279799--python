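"""Exception hierarchy shared across the package."""


class HapgwasError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HapgwasError, ValueError):
    """An argument or configuration value is out of its allowed range."""


class FormatError(HapgwasError, ValueError):
    """A file does not parse under the declared dialect.

    Carries an optional 1-based line number of the offending record.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class EmptyResultError(HapgwasError):
    """An operation produced an empty result where data is required."""


class MonomorphicError(HapgwasError, ValueError):
    """A statistic is undefined because a locus has a single allele."""


class FitError(HapgwasError, RuntimeError):
    """A numerical fit failed to converge; message carries diagnostics."""


class ImputationError(HapgwasError, RuntimeError):
    """Imputation cannot proceed (e.g. a marker with no observed calls)."""
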