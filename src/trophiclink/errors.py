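"""Exception types shared across the pipeline."""


class TrophicLinkError(Exception):
    """Base class for all package errors."""


class ConfigError(TrophicLinkError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(TrophicLinkError):
    """Malformed input table (negative counts, duplicated keys, ...)."""


class SimulationError(TrophicLinkError):
    """Latent dynamics produced a non-finite state."""


class EmbeddingError(TrophicLinkError):
    """No usable delay-embedding rows for the requested model."""


class FitError(TrophicLinkError):
    """Model fitting failed (all optimizer starts, rank deficiency, ...)."""
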