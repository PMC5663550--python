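"""Exception hierarchy for btbquant.

All package errors derive from :class:`BtbQuantError` so callers can catch
pipeline failures with a single except clause while still distinguishing
configuration mistakes from data problems.
"""


class BtbQuantError(Exception):
    """Base class for all btbquant errors."""


class ConfigurationError(BtbQuantError, ValueError):
    """A simulation or run configuration violates its invariants."""


class InputError(BtbQuantError, ValueError):
    """Measured input data violates a precondition (shape, labels, range)."""


class InsufficientDataError(InputError):
    """Too few observations for the requested fit or test."""


class DegenerateInputError(InputError):
    """Input admits no unique solution (e.g. zero variance in the regressor)."""


class ComputationError(BtbQuantError, ArithmeticError):
    """A quantity is undefined for the given values (e.g. zero denominator)."""


class CalibrationError(BtbQuantError, ValueError):
    """A calibration fit failed or violates monotonicity."""


class GenerationError(BtbQuantError, RuntimeError):
    """The synthetic generator could not satisfy its constraints."""


class RangeError(BtbQuantError, ValueError):
    """A value lies outside the calibrated range and extrapolation is off."""
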