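"""Exception hierarchy for vnscluster.

All package errors derive from :class:`VnsClusterError` so callers can catch
one base class; the leaf types match the failure modes of the layer that
raises them (parsing, validation, configuration, solver state).
"""


class VnsClusterError(Exception):
    """Base class for all vnscluster errors."""


class ValidationError(VnsClusterError):
    """Input data violates a dataset invariant (e.g. a zero-norm embedding)."""


class IdError(ValidationError):
    """Missing or duplicate cell identifiers."""


class ParseError(VnsClusterError):
    """A file could not be parsed into the expected tabular shape."""


class FormatError(ParseError):
    """Structural mismatch in a multi-file format (e.g. MTX header vs barcodes)."""


class ConfigError(VnsClusterError):
    """A solver or distance parameter is outside its valid range."""


class SolutionError(VnsClusterError):
    """A centroid vector violates its invariants (duplicates, bad indices)."""


class ShakeError(VnsClusterError):
    """The shake replacement pool is smaller than the requested perturbation."""


class OracleScaleError(VnsClusterError):
    """The exact oracle refuses an instance whose subset count exceeds the limit."""
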