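"""Exception hierarchy for gphsmm."""


class GPHSMMError(Exception):
    """Base class for all gphsmm errors."""


class NumericalDegeneracyError(GPHSMMError):
    """Gram matrix could not be factorized even after diagonal jitter."""


class BookkeepingError(GPHSMMError):
    """Sufficient-statistic bookkeeping was driven inconsistent.

    Raised e.g. when a segment is removed from a model state that does not
    contain it; this always indicates a sampler bug, never a data problem.
    """


class InfeasibleSegmentationError(GPHSMMError):
    """No segmentation of the sequence satisfies the length constraints."""


class ConfigError(GPHSMMError):
    """Invalid run configuration."""


class FormatError(GPHSMMError):
    """Malformed input file."""
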