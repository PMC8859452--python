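"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation/configuration problems (2),
data-insufficiency (3), numerical failures (4).
"""


class SuvtrajError(Exception):
    """Base class for all package errors."""


class CohortValidationError(SuvtrajError, ValueError):
    """Input table violates the longitudinal-table contract."""


class ConfigError(SuvtrajError, ValueError):
    """Invalid or unknown pipeline configuration."""


class InsufficientDataError(SuvtrajError, ValueError):
    """Not enough rows/subjects to run the requested operation."""


class InsufficientNormativeGroupError(InsufficientDataError):
    """Fewer than two amyloid-negative, always-CN subjects available."""


class DegenerateDesignError(SuvtrajError, ValueError):
    """Regression design is degenerate (e.g. all levels identical)."""


class DomainError(SuvtrajError, ValueError):
    """Evaluation requested outside a function's fitted domain."""


class NumericalError(SuvtrajError, ArithmeticError):
    """A numerical routine failed to produce a usable result."""


class PipelineStageError(SuvtrajError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
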