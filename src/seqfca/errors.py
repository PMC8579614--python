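"""Exception hierarchy shared across the package."""


class SeqFcaError(Exception):
    """Base class for all package errors."""


class ValidationError(SeqFcaError):
    """An input table violates a structural invariant (duplicate id,
    dangling edge endpoint, IS-A cycle, conflicting normalization rows...).
    The message names the offending row or identifier."""


class LookupError_(SeqFcaError):
    """A concept or root id is not present in the terminology."""


class EmptySequenceError(SeqFcaError):
    """A name tokenized to an empty word sequence."""


class ConfigurationError(SeqFcaError):
    """An infeasible generator configuration or a missing required input."""


class UndefinedPrecisionError(SeqFcaError):
    """Precision requested over an empty stratum (tp + fp == 0 or total == 0)."""
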