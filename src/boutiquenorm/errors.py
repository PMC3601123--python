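"""Exception hierarchy for validation and pipeline errors."""


class BoutiqueNormError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BoutiqueNormError):
    """A domain-type invariant was violated."""


class MalformedHeaderError(ValidationError):
    """A TSV file header does not match the expected dialect."""


class NonPositiveIntensityError(ValidationError):
    """A probe-level intensity was zero, negative, or non-finite."""


class ProbeCountError(ValidationError):
    """A probe set does not have exactly ``probes_per_set`` probes."""


class UnknownProbeSetError(ValidationError):
    """A probe set referenced by data is absent from the annotation."""


class BackgroundEstimationError(BoutiqueNormError):
    """Background model parameters could not be estimated."""


class ZeroSpreadError(BackgroundEstimationError):
    """Input intensities are all equal; spread cannot be estimated."""


class NumericalDomainError(BoutiqueNormError):
    """A computation left its numerical domain (non-finite output)."""


class InsufficientStableGenesError(BoutiqueNormError):
    """Fewer stable/invariant anchor genes than the method requires."""


class EmptyAbsentSetError(BoutiqueNormError):
    """No probe set is called Absent in every array; RMAPS is inapplicable."""
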