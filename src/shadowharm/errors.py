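"""Exception types shared across the pipeline."""


class ShadowharmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ShadowharmError):
    """A parameter value violates a precondition (bad sizes, thresholds, ...)."""


class DataError(ShadowharmError):
    """Input tables violate an invariant (bad intervals, unknown ids, ...)."""


class StateError(ShadowharmError):
    """An operation was called before its prerequisites were computed."""
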