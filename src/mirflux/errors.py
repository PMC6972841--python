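"""Exception hierarchy shared across stages.

Exit-code mapping in the CLI: ConfigurationError -> 2, QCGateError -> 3.
"""


class MirfluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirfluxError):
    """Invalid configuration value (bad seed, size, probability mass...)."""


class QCGateError(MirfluxError):
    """A library QC gate left a comparison without usable samples."""


class TableParseError(MirfluxError):
    """Malformed row in a TSV fixture; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
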