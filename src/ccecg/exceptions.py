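"""Exception hierarchy for ccecg.

Every error raised by the package derives from :class:`CcEcgError` so callers
can catch the whole family with one clause; the leaf classes mirror the error
contracts of the individual operations.
"""


class CcEcgError(Exception):
    """Base class for all ccecg errors."""


class InvalidParameterError(CcEcgError, ValueError):
    """A parameter is outside its documented range or grid."""


class DegenerateInputError(CcEcgError, ValueError):
    """An input signal is degenerate (e.g. zero variance) for the operation."""


class InvalidInputError(CcEcgError, ValueError):
    """A dataset or argument violates an operation precondition."""


class ShapeInfeasibleError(CcEcgError, ValueError):
    """A network configuration shrinks the temporal axis below one sample."""


class RateUndetectableError(CcEcgError, RuntimeError):
    """No compression-rate spectral peak rises above the noise floor."""


class UndefinedMetricError(CcEcgError, ZeroDivisionError):
    """A ratio metric is requested for an empty class."""


class CorruptDatasetError(CcEcgError, IOError):
    """On-disk dataset is inconsistent (row counts, missing files)."""


class DatasetFormatError(CcEcgError, ValueError):
    """On-disk dataset has malformed content (e.g. non-integer samples)."""


class UnloadableModelError(CcEcgError, IOError):
    """A saved model cannot be restored (missing/mismatched sidecar)."""
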