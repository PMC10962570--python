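"""Exception hierarchy.

Every error zebrafit raises deliberately derives from :class:`ZebrafitError`,
so callers can catch the package's failures without masking programming
errors (plain ``TypeError``/``KeyError`` are still used for API misuse such
as an unknown model id).
"""


class ZebrafitError(Exception):
    """Base class for all zebrafit errors."""


class SchemeParseError(ZebrafitError):
    """A scheme file could not be parsed (malformed row, empty file)."""


class SchemeValidationError(ZebrafitError):
    """An acquisition scheme violates a structural invariant."""


class DimensionError(ZebrafitError):
    """Image and mask spatial shapes do not match."""


class ProtocolError(ZebrafitError):
    """The 4th image dimension does not match the scheme length."""


class DegenerateSignalError(ZebrafitError):
    """A voxel signal is unusable (all zero, or non-finite)."""


class DegenerateDesignError(ZebrafitError):
    """Regression design is degenerate (constant covariate)."""


class SampleSizeError(ZebrafitError):
    """Too few observations for the requested statistic."""


class PairingError(ZebrafitError):
    """Longitudinal observations are not a valid within-subject pair."""


class UndefinedStatisticError(ZebrafitError):
    """The consistency ratio is undefined (zero mean slope)."""


class SummaryError(ZebrafitError):
    """No usable voxels for a map summary or histogram."""


class SimulationSpecError(ZebrafitError):
    """A synthetic-data specification is inconsistent or out of range."""
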