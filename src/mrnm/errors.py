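"""Exception hierarchy shared across the package."""


class MRNMError(Exception):
    """Base class for all package errors."""


class FormatError(MRNMError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(MRNMError):
    """Input data violates a contract (duplicate ids, bad values, ...)."""


class SchemaError(MRNMError):
    """A declared column or config key is missing or ill-typed."""


class ParameterError(MRNMError):
    """A numeric argument is outside its admissible range."""


class AlignmentError(MRNMError):
    """Sample identifiers of two inputs cannot be reconciled."""


class DegenerateTraitError(MRNMError):
    """A trait has no usable variation (constant, zero residual variance)."""


class NotPositiveDefiniteError(MRNMError):
    """A covariance matrix implied by parameters is not positive definite."""


class InitializationError(MRNMError):
    """REML cannot start: covariance not PD at every tried initialization."""


class EmptyPanelError(MRNMError):
    """SNP QC removed every marker."""
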