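"""Exception types used across the simulator."""


class HexfracError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(HexfracError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(HexfracError, RuntimeError):
    """A system is in a state on which the requested operation is undefined."""


class InstabilityError(HexfracError, RuntimeError):
    """The integrator diverged (per-step displacement exceeded one block size)."""

    def __init__(self, block_id: int, step: int, message: str | None = None):
        self.block_id = int(block_id)
        self.step = int(step)
        super().__init__(
            message
            or f"integration diverged at step {step}: block {block_id} moved more "
            "than one block size in a single time step"
        )


class InsufficientDataError(HexfracError, ValueError):
    """Too few data points to perform a fit."""


class FitFailureError(HexfracError, RuntimeError):
    """A nonlinear fit failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, residuals=None):
        self.residuals = residuals
        super().__init__(message)


class ConfigurationError(HexfracError, ValueError):
    """A run configuration failed validation; names the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key '{key}': {message}")
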