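"""Exception hierarchy shared across the package."""


class StepkinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(StepkinError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(StepkinError, ValueError):
    """Too few (or too degenerate) data points for the requested fit."""


class ParseError(StepkinError, ValueError):
    """A file could not be parsed against its expected dialect."""


class SchemaError(StepkinError, ValueError):
    """A table header does not match the expected schema."""


class ConfigError(StepkinError, ValueError):
    """An invalid configuration value."""


class FitError(StepkinError, RuntimeError):
    """A nonlinear fit failed to converge."""


class TrackingError(StepkinError, RuntimeError):
    """A step was lost (or ambiguous) during frame-to-frame tracking."""


class CalibrationError(StepkinError, ValueError):
    """A bond-scheme calibration constraint cannot be satisfied."""


class SimulationError(StepkinError, RuntimeError):
    """Internal inconsistency in a simulation engine (always fatal)."""
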