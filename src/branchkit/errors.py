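"""Exception hierarchy for branchkit.

All package-specific failures derive from :class:`BranchkitError` so callers
can catch one base class at pipeline level while tests assert on the precise
subtype.
"""


class BranchkitError(Exception):
    """Base class for all branchkit errors."""


class StructureParseError(BranchkitError):
    """A structure file could not be read or parsed."""


class EmptyStructureError(BranchkitError):
    """A structure file contained no atoms."""


class MappingError(BranchkitError):
    """A chain-to-subunit mapping is invalid (duplicate label, overlap, ...)."""


class MissingChainError(MappingError):
    """A mapping references a chain absent from the structure."""


class EmptySelectionError(BranchkitError):
    """An atom selection matched nothing where atoms were required."""


class ReferenceAtomError(BranchkitError):
    """A designated reference atom (e.g. Met269 Calpha) is missing or duplicated."""


class PairingError(BranchkitError):
    """Two subunits could not be paired residue-by-residue."""


class DegeneracyError(BranchkitError):
    """A point set is too small or degenerate (collinear) for superposition."""


class GroupingError(BranchkitError):
    """Subunit groups passed to a contact/area query overlap or are empty."""


class ProvenanceError(BranchkitError):
    """Objects from different models were combined."""


class ParameterError(BranchkitError):
    """An out-of-range numeric parameter (negative sigma, zero probe, ...)."""


class RadiusError(BranchkitError):
    """No van der Waals radius is available for an element."""


class ConfigError(BranchkitError):
    """An analysis configuration file is invalid."""
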