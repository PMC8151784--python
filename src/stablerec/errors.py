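"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration field is invalid or infeasible; the message names it."""


class LeakageError(RuntimeError):
    """A held-out or test patient influenced selection or standardization."""


class BackendStateError(RuntimeError):
    """A feature-extraction backend was used before initialization."""
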