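"""Exception hierarchy shared across the toolkit."""


class Seq2TrackError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(Seq2TrackError, ValueError):
    """An architecture or training configuration violates an invariant."""


class ShapeError(Seq2TrackError, ValueError):
    """An array has the wrong shape for the requested operation."""


class EncodingError(Seq2TrackError, ValueError):
    """A sequence contains characters outside the {A,C,G,T,N} alphabet."""


class DataError(Seq2TrackError, ValueError):
    """Input data violates a contract (e.g. negative coverage)."""


class PartitionError(Seq2TrackError, ValueError):
    """A region split cannot be formed as requested."""


class DegenerateMetricError(Seq2TrackError, ValueError):
    """A metric is undefined for the given input (e.g. constant vector)."""


class EvaluationError(Seq2TrackError, ValueError):
    """Evaluation cannot produce any per-track value."""


class CheckpointError(Seq2TrackError, ValueError):
    """A checkpoint file is missing, corrupted, or incompatible."""
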