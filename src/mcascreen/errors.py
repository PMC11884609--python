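"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


class InputError(ValueError):
    """Raised when runtime inputs (frames, label sequences, ...) are invalid."""


class DegenerateObjectError(RuntimeError):
    """Raised when a segmented object is too small or thin to partition."""


class FitError(RuntimeError):
    """Raised when a regression has a singular or otherwise unusable design."""
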