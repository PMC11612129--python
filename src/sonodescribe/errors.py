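"""Exception hierarchy shared across the pipeline."""


class SonodescribeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SonodescribeError):
    """Invalid configuration value (weights, thresholds, sizes)."""


class GeometryError(SonodescribeError):
    """Degenerate or out-of-bounds geometry (boxes, nodules)."""


class InputError(SonodescribeError):
    """Invalid input data (empty manifests, vocabulary mismatches)."""


class ModelStateError(SonodescribeError):
    """Operation requires a fitted/trained model that is not available."""


class TemplateError(SonodescribeError):
    """Report template is missing a required slot."""
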