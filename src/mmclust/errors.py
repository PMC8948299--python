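"""Exception hierarchy shared across the package."""


class MMClustError(Exception):
    """Base class for all package-specific errors."""


class CatalogError(MMClustError):
    """Invalid condition catalog (parse failure, duplicate, prefix nesting)."""


class SimulationError(MMClustError):
    """Synthetic-data generation could not satisfy the requested configuration."""


class ParameterError(MMClustError, ValueError):
    """An operation was called with out-of-range or inconsistent parameters."""


class InputFormatError(MMClustError, ValueError):
    """A data record or file does not conform to the documented format."""


class PipelineError(MMClustError):
    """A pipeline stage failed; the message names the stage."""
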