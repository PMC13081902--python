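"""Exception hierarchy shared across the package."""


class MetalloBSHError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MetalloBSHError):
    """Input violates a documented precondition (empty sequence, zero depth...)."""


class InvalidAlphabetError(InvalidInputError):
    """Sequence contains characters outside the declared alphabet."""


class ConfigError(MetalloBSHError):
    """Inconsistent configuration (duplicate ids, profile position out of range...)."""


class NotFoundError(MetalloBSHError):
    """A requested entity (seed node, metal atom pair) does not exist."""


class InsufficientDataError(InvalidInputError):
    """Too few observations for the requested statistic."""


class GenerationError(MetalloBSHError):
    """A synthetic-data generator could not reach its target within its attempt budget."""
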