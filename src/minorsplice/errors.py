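"""Exception hierarchy shared across the pipeline.

Exit-code contract for the CLI: configuration/format problems map to exit
code 2, analysis failures to exit code 3.
"""


class MinorspliceError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MinorspliceError, ValueError):
    """A function was called with an argument violating its preconditions."""


class FormatError(MinorspliceError, ValueError):
    """An input file failed to parse; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
            if line is not None:
                prefix += f":{line}"
            prefix += ": "
        super().__init__(prefix + message)


class ConsistencyError(MinorspliceError, ValueError):
    """Two inputs that must agree (e.g. keyed tables) do not."""


class UndefinedDistanceError(MinorspliceError, ValueError):
    """Cosine distance requested against an all-zero profile."""


class FitError(MinorspliceError, RuntimeError):
    """Nonlinear fit failed to converge or the model is unidentifiable.

    ``diagnostics`` holds whatever the optimizer reported.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class ConfigError(MinorspliceError, ValueError):
    """A run configuration failed schema validation."""
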