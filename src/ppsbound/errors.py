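"""Exception hierarchy shared across the package."""


class PPSBoundError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PPSBoundError, ValueError):
    """A stimulus/generator/run configuration violates an invariant."""


class SchemaError(PPSBoundError, ValueError):
    """A trial table or config file does not match the declared schema."""


class EstimationError(PPSBoundError, ValueError):
    """A psychometric curve or cell cannot support the requested estimate."""
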