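"""Exception hierarchy shared across the pipeline stages."""


class ChronoclassError(Exception):
    """Base class for all package errors."""


class ConfigError(ChronoclassError):
    """Invalid configuration (bad counts, fractions not summing to 1, ...)."""


class InputError(ChronoclassError):
    """Malformed or inconsistent input data (mismatched ids, missing columns)."""


class ParseError(InputError):
    """A file failed validation; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CalibrationError(ChronoclassError):
    """Scan-to-scan calibration could not be fitted (thin or degenerate support)."""


class NormalizationError(ChronoclassError):
    """Too few features (or otherwise degenerate input) for LOWESS normalization."""


class AssemblyError(ChronoclassError):
    """Cross-array matrix assembly produced an empty result."""


class FitError(ChronoclassError):
    """A per-gene model fit was impossible (e.g. fewer than 2 usable groups)."""


class ScanError(ChronoclassError):
    """A covariate scan could not be run (too few samples with the covariate)."""


class ScreenError(ChronoclassError):
    """The fold-change outlier screen is undefined (tiny or zero-variance pool)."""


class TabulationError(ChronoclassError):
    """Fold-change bin tabulation is undefined (e.g. an empty epoch)."""


class PipelineError(ChronoclassError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
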