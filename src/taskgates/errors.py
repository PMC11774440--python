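"""Exception types shared across the package."""


class TaskGatesError(Exception):
    """Base class for package-specific errors."""


class InvalidConfigurationError(TaskGatesError, ValueError):
    """A configuration is internally inconsistent or infeasible."""


class DimensionError(TaskGatesError, ValueError):
    """Array shapes do not match the declared model dimensions."""


class DomainError(TaskGatesError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InstabilityError(TaskGatesError, RuntimeError):
    """Numerical integration diverged (task loss exceeded the guard value)."""


class InsufficientDataError(TaskGatesError, ValueError):
    """A metric was requested on a run too short to support it."""
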