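"""Exception hierarchy for :mod:`polecarry`."""


class PoleCarryError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PoleCarryError, ValueError):
    """A physical parameter is outside its admissible range."""


class NoSupportError(InvalidParameterError):
    """The vertical contact stiffness is zero: nothing carries the weight."""


class VariantMismatchError(PoleCarryError):
    """A state or parameter set is inconsistent with the active pole variant."""


class RopeConfigurationError(PoleCarryError):
    """A rope angle reached or exceeded 90 deg, where the force law is undefined."""


class NumericalSingularityError(PoleCarryError):
    """The instantaneous equation system is singular or hopelessly ill-conditioned."""


class IntegrationError(PoleCarryError):
    """The ODE integrator failed; carries the last accepted state."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class CalibrationError(PoleCarryError):
    """Step-amplitude calibration could not bracket the requested target."""


class TrajectoryFormatError(PoleCarryError):
    """A trajectory file does not conform to the expected layout."""


class ConfigError(PoleCarryError):
    """An experiment configuration failed validation.

    ``field`` names the offending entry so CLI errors can point at it.
    """

    def __init__(self, message, field=None):
        super().__init__(message)
        self.field = field
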