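"""Exception hierarchy for the gaze-analysis pipeline."""


class GazentropyError(Exception):
    """Base class for all package errors."""


class FormatError(GazentropyError):
    """A file does not match the expected tabular schema."""


class ValidationError(GazentropyError):
    """Input data violate a documented invariant."""


class EmptyInputError(GazentropyError):
    """A required input is empty."""


class DomainError(GazentropyError):
    """An argument is outside the mathematical domain of an operation."""


class TrialInvalidError(GazentropyError):
    """A trial cannot produce a heatmap entropy value (e.g. no fixations)
    and must be excluded from analysis."""


class CalibrationError(GazentropyError):
    """The entropy calibration curve could not be built."""
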