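"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Raised when a generator or pipeline configuration is invalid."""


class InsufficientDataError(ValueError):
    """Raised when a segment has too few retained intervals or valid pairs."""


class LeakageError(RuntimeError):
    """Raised when a patient appears in both the fit and the evaluation data.

    Patient-level leakage inflates every downstream metric; it is a hard
    error, never a warning.
    """
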