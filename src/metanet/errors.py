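"""Exception hierarchy for metanet."""


class MetanetError(ValueError):
    """Base class for all metanet errors."""


class InvalidDemographyError(MetanetError):
    """Demographic parameters are inconsistent or out of range."""


class InvalidMatrixError(MetanetError):
    """A matrix argument violates a precondition (shape, sign, finiteness)."""


class GenerationError(MetanetError):
    """A network generator could not realize the requested structure."""


class HeterogeneousDemographyError(MetanetError):
    """Operation requires identical patches; use hetero_bounds for bounds."""


class UnsupportedSizeError(MetanetError):
    """Problem size exceeds what a report-oriented routine supports."""


class EdgeListError(MetanetError):
    """A network or connectivity file is malformed."""
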