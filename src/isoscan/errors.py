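"""Exception types shared across the pipeline."""


class IsoscanError(Exception):
    """Base class for all isoscan errors."""


class BoundsError(IsoscanError, ValueError):
    """A region-of-interest box does not fit inside its source volume."""


class DegenerateInputError(IsoscanError, ValueError):
    """Input has no usable dynamic range (zero mean, constant volume, ...)."""


class ParameterError(IsoscanError, ValueError):
    """An argument is outside its documented domain."""


class ArchitectureError(IsoscanError, ValueError):
    """A layer stack is malformed or collapses a spatial axis to zero."""


class TrainingError(IsoscanError, RuntimeError):
    """Training cannot proceed (e.g. single-class training set)."""
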