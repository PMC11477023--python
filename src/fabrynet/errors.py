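"""Exception hierarchy shared across the pipeline stages."""


class FabrynetError(Exception):
    """Base class for all package errors."""


class ParseError(FabrynetError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(FabrynetError):
    """Input violated a domain invariant."""


class ConfigError(FabrynetError):
    """A configuration value is out of range or infeasible."""


class SamplerFailureError(FabrynetError):
    """The solution sampler accepted nothing; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class UndefinedScoreError(FabrynetError):
    """A per-solution statistic is undefined (no modulated effectors)."""


class EmptyScreenError(FabrynetError):
    """Variable cleaning removed every variable."""


class SelectionError(FabrynetError):
    """No reference biomarker satisfies the measurability rule."""


class FoldError(FabrynetError):
    """Cross-validation folds cannot be formed from the given labels."""
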