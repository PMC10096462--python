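"""Exception hierarchy for sdsl.

All errors raised by the public API derive from :class:`SdslError` so callers
can catch a single base class. The CLI maps these to exit codes.
"""


class SdslError(Exception):
    """Base class for all sdsl errors."""


class PDBParseError(SdslError):
    """Malformed PDB input; message names the offending line number."""


class EmptyStructureError(SdslError):
    """A structure with zero atoms."""


class QuerySyntaxError(SdslError):
    """Selection grammar error; message includes the token position."""


class IncompleteBackboneError(SdslError):
    """A site is missing one of the N, CA, C backbone atoms."""


class DegenerateGeometryError(SdslError):
    """Collinear or coincident points where an angle/plane is required."""


class UnknownDihedralError(SdslError):
    """A dihedral quadruplet not declared in the library's dihedral_defs."""


class LibraryInvalidError(SdslError):
    """A rotamer library violating its invariants."""


class UnknownElementError(SdslError):
    """An element missing from the Lennard-Jones parameter table."""


class DegenerateWeightsError(SdslError):
    """All posterior weight mass underflowed during reweighting."""


class EmptyEnsembleError(SdslError):
    """All rotamers were trimmed; advise a larger forgive factor or cap."""


class CorruptArchiveError(SdslError):
    """Rotamer-library archive failed a checksum."""


class ArchiveVersionError(SdslError):
    """Rotamer-library archive with an unsupported format version."""


class ModelInconsistencyError(SdslError):
    """Multistate input whose models do not share one topology."""


class UnsupportedResidueError(SdslError):
    """A repack-region residue with no rotamer set available."""


class MissingSiteError(SdslError):
    """A depth-dataset site without a matching spin centroid."""


class UnderDeterminedError(SdslError):
    """Too few depth restraints for a pose fit."""
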