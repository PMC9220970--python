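"""Exception hierarchy shared across the package."""


class SscaError(Exception):
    """Base class for all errors raised by this package."""


class ChainNotFoundError(SscaError):
    """The requested chain id does not exist in the coordinate file."""


class EmptyTraceError(SscaError):
    """The requested chain contains no usable CA atoms."""


class AlignmentError(SscaError):
    """A label string and a trace (or two label strings) differ in length."""


class InvalidLabelError(SscaError):
    """A secondary-structure letter outside the accepted alphabet."""


class ModelFileError(SscaError):
    """A model file is missing, corrupted, or internally inconsistent."""


class DegenerateTrainingError(SscaError):
    """Training data contains fewer than two distinct classes."""


class GenerationError(SscaError):
    """A synthetic-structure generator failed to place atoms without clashes."""
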