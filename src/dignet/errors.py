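"""Exception hierarchy shared across the package."""


class DignetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DignetError, ValueError):
    """An argument or configuration value violates its contract."""


class SchemaError(DignetError, ValueError):
    """A table is missing required columns or has inconsistent node types."""


class MappingError(DignetError, ValueError):
    """A probe has no entry in the probe-to-gene map."""


class SampleSizeError(ParameterError):
    """Too few samples (or events) for the requested computation."""


class ConstantInputError(DignetError, ValueError):
    """A correlation was requested on a constant vector."""


class DegenerateInputError(DignetError, ValueError):
    """Input is structurally degenerate (e.g. all nodes share one degree)."""


class FitError(DignetError, RuntimeError):
    """A model fit failed (no events, non-convergence, no comparable pairs)."""
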