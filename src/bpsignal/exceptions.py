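"""Exception hierarchy.

Validation problems (bad configuration, malformed input tables) raise
:class:`ValidationError`; numerically degenerate designs raise
:class:`DegenerateDesignError`. The CLI maps the former to exit code 2 and
any other pipeline failure to exit code 3.
"""


class BPSignalError(Exception):
    """Base class for all package errors."""


class ValidationError(BPSignalError, ValueError):
    """Invalid configuration or input; the message names the offending field."""


class DegenerateDesignError(BPSignalError):
    """Regression design is degenerate (constant or collinear columns)."""


class CollinearDesignError(DegenerateDesignError):
    """Design matrix condition number beyond threshold."""


class InsufficientDataError(BPSignalError):
    """Too few subjects for the requested estimate."""


class EmptyPanelError(BPSignalError):
    """No subjects retained after filtering."""


class SingularMatrixError(BPSignalError):
    """Covariance submatrix for a method subset is singular."""


class PipelineStageError(BPSignalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
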