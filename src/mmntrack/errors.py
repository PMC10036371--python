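"""Exception hierarchy for mmntrack."""


class MmntrackError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MmntrackError):
    """Invalid paradigm, noise, preprocessing or detection configuration."""


class GenerationError(MmntrackError):
    """A stimulus sequence cannot be realised under the requested constraints."""


class RenderingError(MmntrackError):
    """An ERP component cannot be rendered on the epoch time grid."""


class EmptyConditionError(MmntrackError):
    """A condition has no usable (unrejected) trials."""


class MissingChannelError(MmntrackError):
    """A requested channel is not present in the data."""


class IncompleteDesignError(MmntrackError):
    """A repeated-measures design is missing cells required for the analysis."""
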