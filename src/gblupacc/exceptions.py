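"""Exception hierarchy for gblupacc.

All package errors derive from :class:`GblupaccError` so callers can catch
everything with one clause; the subclasses distinguish bad user input from
numerically degenerate problems and broken state files.
"""


class GblupaccError(Exception):
    """Base class for all gblupacc errors."""


class ValidationError(GblupaccError, ValueError):
    """Invalid argument values (shapes, ranges, duplicate ids, ...)."""


class DimensionError(ValidationError):
    """Mismatched or non-positive dimensions."""


class ParseError(ValidationError):
    """A delimited input table violates the expected dialect."""


class DegenerateInputError(GblupaccError, ValueError):
    """Numerically degenerate input (e.g. all SNPs monomorphic, g_ii <= 0)."""


class NotPositiveDefiniteError(GblupaccError, ValueError):
    """A matrix required to be positive definite failed factorization."""


class InconsistentInputsError(GblupaccError, ValueError):
    """Inputs are individually valid but jointly impossible (e.g. k <= 0,
    reliability far outside [0, 1])."""


class WrongOperationError(GblupaccError, ValueError):
    """The phenotyped/unphenotyped query was dispatched to the wrong routine."""


class StateFormatError(GblupaccError, ValueError):
    """A reference-state file has the wrong magic bytes or version."""


class StateIntegrityError(StateFormatError):
    """A reference-state file is truncated or fails its checksum."""
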