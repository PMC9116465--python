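"""Exception hierarchy for ceiqa."""


class CEIQAError(Exception):
    """Base class for all ceiqa errors."""


class DimensionError(CEIQAError):
    """An input array has an unusable shape or misaligned extents."""


class ParameterError(CEIQAError):
    """An operation received an out-of-range or inconsistent parameter."""


class PreconditionError(CEIQAError):
    """Input data violates a documented precondition (e.g. zero-valued
    center pixels in a ratio-based descriptor)."""


class UnusableImageError(CEIQAError):
    """The circular field of view is too small to yield a valid crop."""


class DataError(CEIQAError):
    """Non-finite features, degenerate targets, or mismatched tables."""


class FingerprintError(CEIQAError):
    """A model was asked to score features whose layout does not match
    the layout it was trained on."""


class ModelFormatError(CEIQAError):
    """A persisted model file is corrupt or has an unknown format version."""
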