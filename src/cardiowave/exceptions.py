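"""Exception types shared across the pipeline."""


class CardiowaveError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CardiowaveError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidLabelError(InvalidArgumentError):
    """Unknown class label."""


class InvalidChannelError(InvalidArgumentError):
    """Channel name not one of the six canonical SCG/GCG axes."""


class NyquistViolationError(InvalidArgumentError):
    """Requested band extends to or beyond the Nyquist frequency."""


class DegenerateLabelsError(InvalidArgumentError):
    """A label vector with fewer than two classes where two are required."""


class DegenerateSplitError(InvalidArgumentError):
    """A train/test split left some class absent from the training side."""


class MalformedFeatureNameError(InvalidArgumentError):
    """Feature name does not encode (channel, statistic, frequency)."""


class InvalidFamilyError(InvalidArgumentError):
    """Unknown classifier family."""


class DataLeakError(CardiowaveError):
    """Subject identity appears on both sides of a subject-wise split."""


class ShapeUnderflowError(CardiowaveError, ValueError):
    """A layer chain produced a non-positive intermediate shape."""


class ShapeMismatchError(InvalidArgumentError):
    """Input tensor shape incompatible with the network specification."""


class StageDependencyError(CardiowaveError):
    """A pipeline stage was requested before its upstream artifacts exist."""
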