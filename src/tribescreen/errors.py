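"""Exception hierarchy shared across the pipeline stages."""


class TribescreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TribescreenError, ValueError):
    """Invalid simulation or run configuration."""


class ParseError(TribescreenError, ValueError):
    """Malformed input file; message names the offending line or id."""


class SchemaError(TribescreenError, ValueError):
    """Required column missing or of the wrong type."""


class NormalizationError(TribescreenError, ValueError):
    """Normalization impossible, e.g. no shared nonzero guides with the reference."""


class ContrastError(TribescreenError, ValueError):
    """Requested condition absent from the sample metadata."""


class DesignError(TribescreenError, ValueError):
    """Validation-library design impossible with the given source manifest."""


class FitError(TribescreenError, RuntimeError):
    """Model fit failed or is degenerate (e.g. all depths zero)."""
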