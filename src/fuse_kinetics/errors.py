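"""Exception types shared across the package."""


class FuseKineticsError(Exception):
    """Base class for all package-specific errors."""


class DegenerateTraceError(FuseKineticsError, ValueError):
    """A dequenching trace cannot be normalized or fitted."""


class DomainError(FuseKineticsError, ValueError):
    """Inputs are outside the physical domain of a model."""


class InconsistentLabelingError(FuseKineticsError, ValueError):
    """Two-step labeling intensities violate their ordering constraint."""


class SchemaError(FuseKineticsError, ValueError):
    """A tabular input is missing required columns."""


class ClassificationError(FuseKineticsError, KeyError):
    """An atom name cannot be resolved by the classifier."""
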