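"""Exception hierarchy for the otolith pipeline.

All pipeline errors derive from :class:`OtolithError` so callers can catch
one base class at the CLI boundary.
"""


class OtolithError(Exception):
    """Base class for all pipeline errors."""


class FormatError(OtolithError, ValueError):
    """A tabular input is malformed (missing column, bad header)."""


class EmptyInputError(OtolithError, ValueError):
    """An operation received no usable data."""


class ParameterError(OtolithError, ValueError):
    """A tuning parameter is out of its admissible range."""


class RoleError(OtolithError, ValueError):
    """A run was used in a role it does not carry (e.g. a sample among blanks)."""


class CoverageError(OtolithError, KeyError):
    """Blank/standard statistics do not cover an isotope present in a run."""


class CalibrationError(OtolithError, ValueError):
    """Standard-bracket calibration is impossible (missing or non-positive standard)."""


class PreconditionError(OtolithError, ValueError):
    """An operation's documented precondition is violated."""


class JoinError(OtolithError, KeyError):
    """A fish id could not be joined against the metadata table."""
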