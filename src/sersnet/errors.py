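"""Shared exception types."""


class ConfigError(ValueError):
    """Invalid configuration value or combination."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested operation (e.g. constant spectrum)."""


class AugmentationError(ValueError):
    """A group cannot be augmented (fewer than ``n_components`` spectra)."""


class StateError(RuntimeError):
    """Operation requires a state the object is not in (e.g. untrained model)."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""
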