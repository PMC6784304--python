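"""Exception types shared across the pipeline stages."""


class HandoverError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HandoverError, ValueError):
    """A precondition on an operation argument was violated."""


class EmptyDataError(HandoverError):
    """A filtering or selection step left no usable data."""


class DegenerateLabelsError(HandoverError, ValueError):
    """A classifier was given fewer than two classes."""


class NotTrainedError(HandoverError, RuntimeError):
    """A model was queried before it was trained."""


class UndefinedNormalizationError(HandoverError, ZeroDivisionError):
    """A normalized quantity has a zero denominator (e.g. all-zero configuration)."""


class RankDeficiencyError(HandoverError, ValueError):
    """A multivariate linear model's error matrix is singular."""


class SchemaError(HandoverError, ValueError):
    """An external data file does not conform to the trajectory/metadata schema."""
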