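"""Exception hierarchy shared across the pipeline stages."""


class MoakitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MoakitError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(MoakitError):
    """A control/calibration signal is unusable (zero, negative, inconsistent)."""


class DegenerateFitError(MoakitError):
    """A curve fit cannot be identified from the data (flat response, no convergence)."""


class InsufficientDataError(MoakitError):
    """Fewer usable points than the operation requires."""


class DependencyError(MoakitError):
    """A required upstream result (e.g. a single-agent fit) is missing."""


class NormalizationError(MoakitError):
    """Count normalization impossible (no guide observed in every sample)."""


class DegenerateNullError(MoakitError):
    """The pseudo-gene null has zero spread; z-scores are undefined."""


class InsufficientControlsError(MoakitError):
    """Too few non-targeting guides to build pseudo-genes."""


class AlignmentError(MoakitError):
    """Gene universes of two score tables do not match."""


class RosterError(MoakitError):
    """A signature is missing a roster hairpin or names an unknown one."""


class DegenerateMeasurementError(MoakitError):
    """A GFP competition measurement sits on a boundary where RI is undefined."""


class UndefinedGRError(MoakitError):
    """GR denominator is zero: the untreated population did not grow."""


class SchemaError(MoakitError):
    """An input file violates its documented schema."""
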