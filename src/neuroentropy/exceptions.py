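"""Exception hierarchy for neuroentropy."""


class NeuroentropyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeuroentropyError):
    """A parameter or config-file value violates the documented schema."""


class FormatError(NeuroentropyError):
    """An input file does not match the expected on-disk format."""


class ValidationError(NeuroentropyError):
    """Inputs are well-formed but semantically inconsistent (labels, shapes, ranges)."""


class AnalysisError(NeuroentropyError):
    """An estimator is undefined for the given data (too few voxels, zero variance, ...)."""
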