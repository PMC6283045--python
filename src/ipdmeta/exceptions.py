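"""Exception hierarchy for ipdmeta."""


class IPDMetaError(Exception):
    """Base class for all ipdmeta errors."""


class ConfigurationError(IPDMetaError):
    """A column mapping or option does not match the supplied data."""


class DataError(IPDMetaError):
    """A value in the input data is malformed (non-binary treatment,
    non-numeric outcome, partially missing baseline, ...)."""


class ValidationError(IPDMetaError):
    """The dataset violates a structural invariant required by the
    requested analysis (e.g. a single-arm trial)."""


class DesignError(IPDMetaError):
    """The fixed-effect design is rank deficient for the requested model."""


class FittingError(IPDMetaError):
    """Linear algebra failure during estimation (singular GLS system)."""


class InferenceError(IPDMetaError):
    """A confidence-interval correction could not be computed."""


class UsageError(IPDMetaError):
    """An operation was requested for a fit it does not apply to
    (e.g. a small-sample correction after ML estimation)."""
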