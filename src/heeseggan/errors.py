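"""Exception types shared across the package."""


class HeeSegGanError(Exception):
    """Base class for package errors."""


class ConfigurationError(HeeSegGanError, ValueError):
    """An invalid configuration value."""


class EmptyMaskError(HeeSegGanError, ValueError):
    """An operation requiring a nonempty mask received an empty one."""


class ShapeError(HeeSegGanError, ValueError):
    """Array shapes incompatible with the requested operation."""


class TrainingDiverged(HeeSegGanError, RuntimeError):
    """A non-finite loss was encountered; carries a diagnostic snapshot."""

    def __init__(self, message: str, snapshot: dict | None = None):
        super().__init__(message)
        self.snapshot = snapshot or {}
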