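"""Exception hierarchy shared across the package."""


class ColexnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ColexnetError):
    """A column mapping, threshold, or enum value is invalid."""


class EmptyInputError(ColexnetError):
    """A wordlist read yielded zero admissible rows."""


class CapabilityError(ColexnetError):
    """A requested pluggable backend (e.g. a community algorithm) is unavailable."""


class GenerationError(ColexnetError):
    """The synthetic-lexicon sampler could not satisfy its constraints."""
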