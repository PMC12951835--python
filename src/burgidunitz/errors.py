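"""Exception hierarchy for active-site geometry analysis."""


class BurgiDunitzError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(BurgiDunitzError):
    """A coordinate file contained no ATOM/HETATM records."""


class ResidueNotFoundError(BurgiDunitzError, LookupError):
    """A residue addressed by (chain, number, insertion code) is absent."""


class AtomNotFoundError(BurgiDunitzError, LookupError):
    """A named atom is absent from the addressed residue."""


class AmbiguousAltlocError(BurgiDunitzError):
    """An explicit altloc request matched zero or multiple conformers."""


class IncompleteLigandError(BurgiDunitzError):
    """A ligand residue lacks one of the four electrophile-frame atoms."""


class DegenerateGeometryError(BurgiDunitzError):
    """Collinear/coincident points make a geometric parameter undefined."""


class ConstructionError(BurgiDunitzError):
    """A synthetic fixture specification admits no solution."""


class ManifestError(BurgiDunitzError):
    """A survey manifest is unreadable or malformed."""
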