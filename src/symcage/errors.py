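"""Exception hierarchy for symcage."""


class SymcageError(Exception):
    """Base class for all symcage errors."""


class UnknownSymmetryError(SymcageError):
    """Requested point-group symbol or architecture is not recognized."""


class GroupAxisError(SymcageError):
    """An axis/order combination is not realized by the requested group."""


class BuildingBlockError(SymcageError):
    """A building block violates the homomer or cyclic-symmetry contract."""


class AsymmetricBlockError(BuildingBlockError):
    """Cyclic-symmetry fit exceeded the configured tolerance."""


class MotifError(SymcageError):
    """Motif geometry is undefined or missing for the requested operation."""


class DockingError(SymcageError):
    """Invalid docking request (order mismatch, non-canonical block...)."""


class StructureIOError(SymcageError):
    """Structure file could not be parsed or written."""


class AnalysisError(SymcageError):
    """Structure comparison inputs are incompatible."""


class SequenceError(SymcageError):
    """A sequence contains characters outside the amino-acid alphabet."""


class ConfigError(SymcageError):
    """Configuration failed schema validation."""
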