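"""Exception hierarchy.

Every error raised by this package derives from :class:`EEGMFCCError` so
callers can catch the whole family; most also derive from the matching
builtin (ValueError/KeyError) for idiomatic handling.
"""


class EEGMFCCError(Exception):
    """Base class for all package errors."""


class FormatError(EEGMFCCError, ValueError):
    """Unparseable or empty input file."""


class StructureError(EEGMFCCError, ValueError):
    """Inconsistent molecular structure (duplicate atoms, missing cut-site atoms...)."""


class ResidueLookupError(EEGMFCCError, KeyError):
    """A residue index or name does not resolve."""


class AmbiguityError(EEGMFCCError, ValueError):
    """A selection matches more than one candidate and no qualifier was given."""


class RoleError(EEGMFCCError, ValueError):
    """A residue does not have the role an operation requires."""


class RangeError(EEGMFCCError, ValueError):
    """An index is outside the range an operation is defined on."""


class GeometryError(EEGMFCCError, ValueError):
    """Degenerate geometry (coincident atoms, zero-length bond direction)."""


class ArgumentError(EEGMFCCError, ValueError):
    """Invalid argument (empty collection, length mismatch...)."""


class ChargeModelError(EEGMFCCError, KeyError):
    """An atom cannot be resolved to a point charge."""


class SingularityError(EEGMFCCError, ValueError):
    """Zero interparticle distance in a Coulomb sum."""


class CapabilityError(EEGMFCCError, ValueError):
    """An engine does not support a requested property."""


class EngineError(EEGMFCCError, RuntimeError):
    """A per-fragment engine run failed; carries the fragment label."""


class ValidationError(EEGMFCCError, ValueError):
    """Internally inconsistent result (e.g. omega contradicting energies)."""


class SchemaError(EEGMFCCError, ValueError):
    """Missing or malformed fields in an interchange file."""


class ProvenanceError(EEGMFCCError, ValueError):
    """Inputs were produced under the wrong conditions (e.g. embedded results
    fed to the embedding-free decomposition)."""


class CompletenessError(EEGMFCCError, ValueError):
    """Required fragment results are missing; message lists absent labels."""


class AlignmentError(EEGMFCCError, ValueError):
    """Per-atom arrays do not share the same atom ordering/length."""


class ConstructionError(EEGMFCCError, ValueError):
    """A synthetic structure could not be built to the requested geometry."""
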