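"""Ligand → electrophile-frame mapping and oxyanion-hole orientation.

The attacked group is the side-chain amide of Asn/Gln (δ or ε position) or
the carboxylate of Asp/Glu acting as a stand-in for it.  For acid ligands the
two terminal oxygens are crystallographically interchangeable, so the roles
"carbonyl O" and "amide N" are assigned by geometry: the oxygen sitting in
the oxyanion hole (the hydrogen-bond donor constellation that stabilizes the
developing oxyanion) plays the carbonyl role, the other stands in for the
amide nitrogen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import DegenerateGeometryError, IncompleteLigandError
from .structure_io import AtomRecord, ResidueKey, StructureModel, select_atom


class LigandKind(str, Enum):
    """Ligand chemistry; determines atom-name map and stereochemical handling."""

    L_ASN = "L-ASN"
    L_ASP = "L-ASP"
    L_GLN = "L-GLN"
    L_GLU = "L-GLU"
    D_ASN = "D-ASN"
    D_ASP = "D-ASP"

    @property
    def is_acid(self) -> bool:
        """Carboxylate ligand: the second oxygen stands in for the amide N."""
        return self in (LigandKind.L_ASP, LigandKind.L_GLU, LigandKind.D_ASP)

    @property
    def is_d_enantiomer(self) -> bool:
        return self in (LigandKind.D_ASN, LigandKind.D_ASP)

    @property
    def residue_name(self) -> str:
        """Deposited 3-letter code (D-amino acids use their own codes)."""
        return _RESIDUE_NAMES[self]

    @property
    def atom_names(self) -> tuple[str, str, str, str]:
        """(C_el, O_carbonyl, N_amide-role, C_chain) PDB v3 atom names."""
        return _ATOM_NAMES[self]


_RESIDUE_NAMES = {
    LigandKind.L_ASN: "ASN",
    LigandKind.L_ASP: "ASP",
    LigandKind.L_GLN: "GLN",
    LigandKind.L_GLU: "GLU",
    LigandKind.D_ASN: "DSG",
    LigandKind.D_ASP: "DAS",
}

# delta-position electrophiles (Asn/Asp), epsilon-position (Gln/Glu)
_ATOM_NAMES = {
    LigandKind.L_ASN: ("CG", "OD1", "ND2", "CB"),
    LigandKind.D_ASN: ("CG", "OD1", "ND2", "CB"),
    LigandKind.L_ASP: ("CG", "OD1", "OD2", "CB"),
    LigandKind.D_ASP: ("CG", "OD1", "OD2", "CB"),
    LigandKind.L_GLN: ("CD", "OE1", "NE2", "CG"),
    LigandKind.L_GLU: ("CD", "OE1", "OE2", "CG"),
}

# PDB v2 aliases accepted on read (v2 used e.g. "AD1"/"AD2" for ambiguous
# Asn OD1/ND2); mapped per requested v3 name
_V2_ALIASES = {
    "OD1": ("AD1",),
    "ND2": ("AD2",),
    "OE1": ("AE1",),
    "NE2": ("AE2",),
}

#: a per-donor contact beyond this (Å) is logged as strained, not rejected
HBOND_CUTOFF = 3.5


@dataclass(frozen=True)
class ElectrophileSite:
    """The four-atom frame of the trigonal electrophile."""

    c_el: AtomRecord
    o_carbonyl: AtomRecord
    n_amide: AtomRecord  # amide N, or the second acid O playing its role
    c_chain: AtomRecord
    kind: LigandKind
    swapped: bool = False  # True when O roles were exchanged vs deposited names


@dataclass(frozen=True)
class NucleophileSite:
    """The attacking Ser/Thr hydroxyl oxygen."""

    residue: ResidueKey
    o_nuc: AtomRecord
    role: str = "primary"  # "primary" | "secondary"


@dataclass(frozen=True)
class OxyanionHole:
    """1–3 hydrogen-bond donor atoms (main-chain N or side-chain O)."""

    donors: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if not self.donors:
            raise ValueError("oxyanion hole requires at least one donor atom")

    def mean_distance(self, point: np.ndarray) -> float:
        return float(
            np.mean([np.linalg.norm(d.position - point) for d in self.donors])
        )


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reason: str = ""


def _resolve_with_aliases(
    model: StructureModel, key: ResidueKey, name: str
) -> AtomRecord:
    try:
        return select_atom(model, key, name)
    except Exception:
        for alias in _V2_ALIASES.get(name, ()):
            try:
                return select_atom(model, key, alias)
            except Exception:
                continue
        raise


def resolve_electrophile(
    model: StructureModel, ligand: ResidueKey, kind: LigandKind
) -> ElectrophileSite:
    """Map the ligand residue onto the four-atom electrophile frame.

    Returned with ``swapped=False``; for acid ligands the second carboxylate
    oxygen provisionally occupies the amide-nitrogen role until
    :func:`orient_by_oxyanion_hole` fixes the assignment.
    """
    names = kind.atom_names
    atoms = []
    for name in names:
        try:
            atoms.append(_resolve_with_aliases(model, ligand, name))
        except Exception as exc:
            raise IncompleteLigandError(
                f"ligand {ligand} ({kind.value}) lacks atom {name}: {exc}"
            ) from exc
    c_el, o_c, n_a, c_c = atoms
    u = n_a.position - o_c.position
    v = c_c.position - o_c.position
    if np.linalg.norm(np.cross(u, v)) < 1e-8:
        raise DegenerateGeometryError(f"collinear substituents in ligand {ligand}")
    return ElectrophileSite(
        c_el=c_el, o_carbonyl=o_c, n_amide=n_a, c_chain=c_c, kind=kind
    )


class AmideOrientationWarning(UserWarning):
    """The deposited amide N sits closer to the oxyanion hole than the O."""


def orient_by_oxyanion_hole(
    site: ElectrophileSite, hole: OxyanionHole
) -> tuple[ElectrophileSite, bool]:
    """Assign the carbonyl-oxygen role using the oxyanion hole.

    For acid ligands, whichever terminal oxygen has the smaller mean distance
    to the hole donors takes the carbonyl role; ``swap_applied`` reports
    whether that exchanged the deposited assignment.  For amide ligands no
    atoms are moved, but a warning is raised if the amide nitrogen is the
    atom in the hole (a deposition error the survey flags).

    Idempotent: the orientation depends only on geometry, so re-applying it
    never swaps again.
    """
    if hole is None:
        raise ValueError("oxyanion hole donors are required for orientation")
    d_o = hole.mean_distance(site.o_carbonyl.position)
    d_n = hole.mean_distance(site.n_amide.position)
    for donor in hole.donors:
        closest = min(d_o, d_n)
        if closest > HBOND_CUTOFF:
            warnings.warn(
                f"strained oxyanion contact: nearest candidate at {closest:.2f} Å "
                f"from donor {donor.atom_name}",
                UserWarning,
                stacklevel=2,
            )
            break
    if not site.kind.is_acid:
        if d_n < d_o:
            warnings.warn(
                f"amide ligand {site.c_el.residue_key}: N_amide is in the "
                "oxyanion hole (misoriented deposition?)",
                AmideOrientationWarning,
                stacklevel=2,
            )
        return site, False
    if d_n < d_o:
        swapped = replace(
            site,
            o_carbonyl=site.n_amide,
            n_amide=site.o_carbonyl,
            swapped=not site.swapped,
        )
        return swapped, True
    return site, False


def screen_nucleophile(
    atom: AtomRecord, occupancy_min: float = 1.0, adp_max: float = 100.0
) -> ScreenResult:
    """Order criterion for the nucleophile atom.

    Passes iff occupancy ≥ ``occupancy_min`` and ADP strictly < ``adp_max``
    (defaults: full occupancy, B < 100 Å²).
    """
    reasons = []
    if atom.occupancy < occupancy_min:
        reasons.append(f"partial occupancy {atom.occupancy:.2f} < {occupancy_min:.2f}")
    if not atom.adp < adp_max:
        reasons.append(f"ADP {atom.adp:.1f} Å² >= {adp_max:.1f} Å²")
    return ScreenResult(passed=not reasons, reason="; ".join(reasons))
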