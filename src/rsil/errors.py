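"""Exception hierarchy shared across the pipeline."""


class RSILError(Exception):
    """Base class for all errors raised by this package."""


class InvalidMeasurementError(RSILError, ValueError):
    """A measured value lies outside its physical domain."""


class SingularInversionError(RSILError, ZeroDivisionError):
    """The mixing-model inversion is singular (measured == substrate signature)."""


class DegeneratePoolError(RSILError, ValueError):
    """Total carbon pool is empty; mixing is undefined."""


class InvalidLabelError(RSILError, ValueError):
    """Buffer label is not distinguishable from the substrate signature."""


class InsufficientDataError(RSILError, ValueError):
    """Too few data points for the requested estimate."""


class UnitMismatchError(RSILError, ValueError):
    """Rate estimates with incompatible units or intervals were combined."""


class ConfigurationError(RSILError, ValueError):
    """Experiment constants are inconsistent or non-physical."""


class SimulationInfeasibleError(RSILError, ValueError):
    """Requested simulation violates a physical constraint (e.g. sulfate < 0)."""


class ParseError(RSILError, ValueError):
    """Input file does not conform to the documented schema."""
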