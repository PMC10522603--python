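"""Exception hierarchy shared across the package."""


class RemcmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RemcmError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ConsistencyError(RemcmError):
    """Cross-file or cross-object invariant violated (labels, ordering, shape)."""


class DegenerateInputError(RemcmError):
    """An input has no usable variation (constant column, zero variance)."""


class ParameterError(RemcmError, ValueError):
    """An argument is outside its admissible range."""


class StabilityError(RemcmError):
    """Simulated dynamics diverged; coefficients are too large for the horizon."""


class UnderDeterminedError(RemcmError):
    """Fewer design rows than columns; the regression is not identifiable."""
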