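"""Exception hierarchy for the dosimetry pipeline.

Every stage raises a subclass of :class:`MouseDosimError` so callers can
distinguish bad user input from inconsistent data or numerical failure.
"""


class MouseDosimError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MouseDosimError, ValueError):
    """A value violates a documented precondition (negative time, zero mass, ...)."""


class ParseError(MouseDosimError, ValueError):
    """A data file could not be parsed; the message names the offending row."""


class CalibrationStateError(MouseDosimError, RuntimeError):
    """Calibration applied to an image that is already calibrated (or vice versa)."""


class ConfigurationError(MouseDosimError, KeyError):
    """A referenced compartment, density, or dose-factor column is not configured."""


class DataInconsistencyError(MouseDosimError, ValueError):
    """Inputs are mutually inconsistent beyond tolerance (e.g. organ TIACs
    exceeding the whole-body TIAC by more than the allowed deficit)."""


class FitError(MouseDosimError, RuntimeError):
    """Nonlinear fit failed to converge; carries the initial estimates."""

    def __init__(self, message, initial=None):
        super().__init__(message)
        self.initial = initial


class DegenerateFitError(FitError):
    """The curve contains no information to fit (e.g. identically zero)."""


class DomainError(MouseDosimError, ValueError):
    """A physical quantity lies outside the tabulated/validated domain."""


class SpecificationError(MouseDosimError, ValueError):
    """A synthetic-phantom specification is geometrically invalid."""
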