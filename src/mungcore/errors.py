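"""Exception hierarchy for mungcore.

Validation problems are separated from computation and I/O problems so the
command-line tools can map them to distinct exit codes.
"""


class MungcoreError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MungcoreError):
    """A table does not match the expected columns or value domains."""


class ParseError(MungcoreError):
    """A cell could not be parsed into the type its descriptor requires."""


class DesignError(MungcoreError):
    """The field layout violates augmented-block-design structure."""


class UniquenessError(MungcoreError):
    """Duplicate identifiers where unique ones are required."""


class ConfigError(MungcoreError):
    """An invalid generator or pipeline configuration."""


class ComputationError(MungcoreError):
    """A statistic is undefined for the given input (degenerate data)."""


class InfeasibleError(MungcoreError):
    """A constraint set that no core of the requested size can satisfy."""
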