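"""Exception types shared across the package."""


class CorollaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CorollaError):
    """Input does not conform to the landmark template or file schema."""


class LandmarkParseError(CorollaError):
    """A landmark file could not be parsed (carries the offending line)."""


class DegenerateGeometryError(CorollaError):
    """A geometric construction is undefined for this configuration."""


class InsufficientSampleError(CorollaError):
    """Too few specimens (or groups) for the requested analysis."""


class CoverageError(CorollaError):
    """Tree tips and specimen species do not match."""
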