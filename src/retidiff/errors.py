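"""Exception hierarchy shared across the package."""


class RetidiffError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RetidiffError):
    """A file could not be parsed in any supported format."""


class ConfigurationError(RetidiffError):
    """Required metadata or configuration is missing or inconsistent."""


class DegenerateInputError(RetidiffError):
    """Input carries no usable signal (e.g. a constant image)."""


class DegenerateScaleError(RetidiffError):
    """A distance range collapsed to zero, so no kernel scale can be set."""


class ValidationError(RetidiffError):
    """A domain invariant was violated (ordering, sign, shape)."""


class IsolatedNodeError(RetidiffError):
    """A graph node has no neighbour within the kernel radius."""
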