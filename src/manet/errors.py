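"""Exception hierarchy shared across the package."""


class MANetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MANetError, ValueError):
    """Raised when runtime data violates an operation's precondition."""


class InvalidSpecError(MANetError, ValueError):
    """Raised when a declarative spec (network, scene, tiling) is inconsistent."""


class ConfigError(MANetError, ValueError):
    """Raised for malformed run configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class CheckpointMismatchError(MANetError, ValueError):
    """Raised when a checkpoint's architecture hash differs from the requested spec."""


class GenerationError(MANetError, RuntimeError):
    """Raised when synthetic scene placement cannot satisfy the requested spec."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} nuclei (placed {achieved}); "
            "loosen density, size, or overlap constraints"
        )


class UndefinedMetricError(MANetError, ValueError):
    """Raised when a metric is undefined for the given data (e.g. single-class ROC)."""
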