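"""Exception hierarchy.

Everything derives from :class:`AfmStoichError` so callers can catch the
package's failures with one clause; contract violations additionally derive
from ``ValueError`` where the bad input is a plain argument.
"""


class AfmStoichError(Exception):
    """Base class for all errors raised by afmstoich."""


class InvalidSpecError(AfmStoichError, ValueError):
    """A simulation specification violates its invariants."""


class PlacementError(AfmStoichError):
    """Particles could not all be placed at the requested separation."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} particles at the requested "
            "minimum separation"
        )


class FlatteningError(AfmStoichError):
    """Background flattening failed (e.g. every pixel rejected)."""


class ContractError(AfmStoichError, ValueError):
    """An operation was called outside its stated precondition."""


class FormatError(AfmStoichError, ValueError):
    """A file does not conform to the expected on-disk format."""


class FitError(AfmStoichError):
    """Nonlinear histogram fit failed to converge after bounded restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class DegenerateFitError(FitError):
    """A fitted component collapsed below the histogram resolution."""


class ConfigError(AfmStoichError, ValueError):
    """A pipeline configuration is invalid; the message names the field."""


class PipelineError(AfmStoichError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
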