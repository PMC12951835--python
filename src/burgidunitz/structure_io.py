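"""Minimal structure model on top of legacy-PDB coordinate files.

The analysis only ever needs point coordinates addressed by
(chain, residue number, insertion code, atom name, altloc) together with
occupancy and the atomic displacement parameter (B-factor), so the model is a
flat, ordered collection of :class:`AtomRecord` per chain.  Parsing and
serialization of the PDB format itself are delegated to gemmi; this module
adds deterministic atom selection with an explicit altloc policy.

Only the first model of a multi-model file is read: the survey corpus is
crystallographic, where a single model is the norm.  Hydrogens and waters are
parsed like any other atom but are never requested by downstream geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

from .errors import (
    AmbiguousAltlocError,
    AtomNotFoundError,
    EmptyStructureError,
    ResidueNotFoundError,
)

AltlocPolicy = Literal["highest-occupancy", "explicit"]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record in the orthogonal Å frame of the file."""

    atom_name: str
    altloc: str  # single character, "" when the atom has no altloc
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str  # "" when blank
    position: np.ndarray  # shape (3,), Å
    occupancy: float
    adp: float  # isotropic B-factor, Å²
    element: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or malformed position for {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.adp < 0.0:
            raise ValueError(f"negative ADP {self.adp}")

    @property
    def residue_key(self) -> "ResidueKey":
        return ResidueKey(
            chain_id=self.chain_id,
            residue_number=self.residue_number,
            insertion_code=self.insertion_code,
            residue_name=self.residue_name,
        )


@dataclass(frozen=True)
class ResidueKey:
    """Address of one residue within a model.

    ``residue_name`` is an optional consistency check: when non-empty, lookups
    verify the residue found under (chain, number, icode) carries that name.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def __str__(self) -> str:
        name = self.residue_name or "*"
        return f"{self.chain_id}/{name}/{self.residue_number}{self.insertion_code}"


@dataclass
class StructureModel:
    """Ordered atoms of one (crystallographic) model, grouped by chain."""

    structure_id: str
    resolution: float | None = None  # Å; None when the header carries none
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in {self.structure_id}")
            seen.add(key)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def iter_residue_atoms(self, key: ResidueKey) -> Iterator[AtomRecord]:
        for a in self.atoms:
            if (
                a.chain_id == key.chain_id
                and a.residue_number == key.residue_number
                and a.insertion_code == key.insertion_code
            ):
                if key.residue_name and a.residue_name != key.residue_name:
                    raise ResidueNotFoundError(
                        f"residue at {key.chain_id}/{key.residue_number} is "
                        f"{a.residue_name}, expected {key.residue_name}"
                    )
                yield a


def read_structure(path: str | Path) -> StructureModel:
    """Read a legacy-PDB file into a :class:`StructureModel`.

    Coordinates are preserved to the 0.001 Å precision of the format and the
    resolution is taken from the REMARK 2 header when present.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    EmptyStructureError
        If the file contains no ATOM/HETATM records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no coordinate records")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            for atom in res:
                altloc = atom.altloc if atom.altloc not in ("\0", " ") else ""
                atoms.append(
                    AtomRecord(
                        atom_name=atom.name,
                        altloc=altloc,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=icode,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        adp=max(atom.b_iso, 0.0),
                        element=atom.element.name,
                        is_hetero=(res.het_flag == "H"),
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path} contains no coordinate records")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    if math.isnan(st.resolution or 0.0):
        resolution = None
    return StructureModel(structure_id=path.stem, resolution=resolution, atoms=atoms)


def select_atom(
    model: StructureModel,
    key: ResidueKey,
    atom_name: str,
    altloc_policy: AltlocPolicy = "highest-occupancy",
    altloc: str | None = None,
) -> AtomRecord:
    """Resolve one atom under an explicit altloc policy.

    With ``highest-occupancy`` (the default, matching the survey's exclusion
    of disordered sites) occupancy ties are broken by altloc identifier order,
    which makes the selection deterministic.  With ``explicit`` the requested
    ``altloc`` must match exactly one conformer; the blank altloc ``""``
    matches an un-lettered atom.
    """
    residue_atoms = list(model.iter_residue_atoms(key))
    if not residue_atoms:
        raise ResidueNotFoundError(f"no residue {key} in {model.structure_id}")
    candidates = [a for a in residue_atoms if a.atom_name == atom_name]
    if not candidates:
        raise AtomNotFoundError(f"no atom {atom_name} in residue {key}")
    if altloc_policy == "explicit":
        if altloc is None:
            raise AmbiguousAltlocError("explicit policy requires an altloc id")
        matches = [a for a in candidates if a.altloc == altloc]
        if len(matches) != 1:
            raise AmbiguousAltlocError(
                f"altloc {altloc!r} matched {len(matches)} conformers of "
                f"{atom_name} in {key}"
            )
        return matches[0]
    # highest occupancy, ties by altloc identifier
    return sorted(candidates, key=lambda a: (-a.occupancy, a.altloc))[0]


def list_residues(
    model: StructureModel, residue_names: Iterable[str]
) -> list[ResidueKey]:
    """All residues whose 3-letter code is in ``residue_names``.

    Returned in chain order, then sequence order, as they appear in the file.
    Used to locate candidate ligands (ASN/ASP/GLN/GLU and the D-enantiomer
    codes DSG/DAS) in a survey model.
    """
    names = set(residue_names)
    seen: set[tuple] = set()
    out: list[ResidueKey] = []
    for a in model.atoms:
        if a.residue_name in names:
            ident = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
            if ident not in seen:
                seen.add(ident)
                out.append(a.residue_key)
    out.sort(key=lambda k: (k.chain_id, k.residue_number, k.insertion_code))
    return out


def residue_positions(
    model: StructureModel, key: ResidueKey, atom_names: Sequence[str]
) -> dict[str, AtomRecord]:
    """Convenience: resolve several atoms of one residue at once."""
    return {name: select_atom(model, key, name) for name in atom_names}
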