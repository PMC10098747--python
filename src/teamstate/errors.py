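"""Exception hierarchy shared across the package."""


class TeamstateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TeamstateError):
    """A simulation or training configuration violates its invariants."""


class CalibrationError(TeamstateError):
    """A transition-matrix calibration target is infeasible."""


class ValidationError(TeamstateError):
    """Data violates a structural invariant (feature logic, track lengths)."""


class SchemaError(TeamstateError):
    """An input file is missing required columns or has malformed values."""


class NotFittedError(TeamstateError):
    """A model was queried before being fitted."""
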