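"""Exception hierarchy shared across the package.

All errors raised on bad scientific input derive from :class:`MemqaError`
so callers (and the CLI) can distinguish data problems from bugs.
"""


class MemqaError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(MemqaError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(MemqaError):
    """A structure contains no usable C-alpha atoms."""


class TopologyError(MemqaError):
    """A topology annotation is missing, malformed, or inconsistent."""


class RegionError(MemqaError):
    """A residue region/selection resolves to nothing usable."""


class InsufficientEndpointsError(MemqaError):
    """Too few membrane-side endpoint residues to compute a thickness."""


class UnderdeterminedError(MemqaError):
    """Superposition is underdetermined (too few or degenerate points)."""


class AlignmentError(MemqaError):
    """Structural alignment cannot be computed on the given inputs."""


class DomtblParseError(MemqaError):
    """An hmmsearch per-domain table line is malformed."""


class SequenceError(MemqaError):
    """An amino-acid sequence contains invalid characters."""


class ConfigError(MemqaError):
    """A run or library configuration is invalid."""
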