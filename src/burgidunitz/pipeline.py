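"""Survey engine: manifest-driven curation, orientation and geometry.

A manifest row addresses one active-site case: structure file, chain, the two
candidate nucleophiles (primary = the catalytic candidate on the flexible
gating element / N-terminal Thr / first S-K tandem; secondary = the
alternative), the ligand and its chemical kind, and the oxyanion-hole donor
atoms.  The manifest is the single source of residue numbering per homolog —
no sequence alignment is attempted.

Inclusion rules applied per case (reasons are accumulated, not
short-circuited):

* resolution ≤ 3.0 Å,
* ordered nucleophile (full occupancy, ADP < 100 Å²) — waived when the
  manifest pins an explicit altloc, which marks the manually vetted
  alternative-conformation transition-state cases,
* for the class 1 primary candidate only, attack distance d ≤ 4 Å (an open
  gating loop parks the candidate far from the ligand and is
  non-productive),
* ligand kind within the six-member whitelist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .electrophile import (
    LigandKind,
    NucleophileSite,
    OxyanionHole,
    orient_by_oxyanion_hole,
    resolve_electrophile,
    screen_nucleophile,
)
from .errors import AmbiguousAltlocError, BurgiDunitzError, ManifestError
from .geometry import DEFAULT_DEGENERACY_TOL, AttackGeometry, compute_attack
from .structure_io import ResidueKey, StructureModel, read_structure, select_atom

logger = logging.getLogger("burgidunitz")

PRIMARY, SECONDARY = "primary", "secondary"


@dataclass(frozen=True)
class AtomAddress:
    """``chain/resname/resnum[icode]/atom`` address of one atom."""

    residue: ResidueKey
    atom_name: str

    def __str__(self) -> str:
        return f"{self.residue}/{self.atom_name}"


def parse_residue_address(text: str) -> ResidueKey:
    parts = text.strip().split("/")
    if len(parts) != 3:
        raise ManifestError(f"bad residue address {text!r}, want CHAIN/RESNAME/NUM")
    chain, resname, num = parts
    icode = ""
    if num and num[-1].isalpha():
        num, icode = num[:-1], num[-1]
    return ResidueKey(
        chain_id=chain,
        residue_number=int(num),
        insertion_code=icode,
        residue_name="" if resname in ("*", "") else resname,
    )


def parse_atom_address(text: str) -> AtomAddress:
    parts = text.strip().rsplit("/", 1)
    if len(parts) != 2:
        raise ManifestError(f"bad atom address {text!r}, want CHAIN/RESNAME/NUM/ATOM")
    return AtomAddress(residue=parse_residue_address(parts[0]), atom_name=parts[1])


@dataclass(frozen=True)
class Thresholds:
    """Curation thresholds, defaulting to the survey's values."""

    resolution_max: float = 3.0
    fge_max_d: float = 4.0
    occupancy_min: float = 1.0
    adp_max: float = 100.0
    degeneracy_tol: float = DEFAULT_DEGENERACY_TOL


@dataclass(frozen=True)
class ManifestEntry:
    structure_id: str
    path: str
    asparaginase_class: int  # 1, 2, 3; 0 = unclassified
    subtype: str  # "I" | "II" | "s" | "none"
    chain_id: str
    primary_nucleophile: AtomAddress
    ligand: ResidueKey
    ligand_kind: str  # validated against LigandKind at analysis time
    oxyanion_donors: tuple[AtomAddress, ...]
    secondary_nucleophile: AtomAddress | None = None
    altloc_override: str = ""
    resolution: float | None = None
    notes: str = ""


@dataclass(frozen=True)
class FilterStatus:
    included: bool
    reasons: tuple[str, ...] = ()

    def __str__(self) -> str:
        return "included" if self.included else "excluded(" + "; ".join(self.reasons) + ")"


@dataclass(frozen=True)
class CaseResult:
    entry: ManifestEntry
    nucleophile_role: str  # "primary" | "secondary"
    geometry: AttackGeometry | None
    swap_applied: bool
    filter_status: FilterStatus
    error: str = ""


def apply_filters(
    entry: ManifestEntry,
    model: StructureModel,
    geometry: AttackGeometry | None,
    nucleophile: NucleophileSite | None = None,
    role: str = PRIMARY,
    thresholds: Thresholds = Thresholds(),
) -> FilterStatus:
    """Inclusion/exclusion decision for one case; reasons accumulate."""
    reasons: list[str] = []
    resolution = entry.resolution if entry.resolution is not None else model.resolution
    if resolution is None:
        reasons.append("resolution-unknown")
    elif resolution > thresholds.resolution_max:
        reasons.append(f"resolution {resolution:.2f} > {thresholds.resolution_max:.1f} A")
    try:
        LigandKind(entry.ligand_kind)
    except ValueError:
        reasons.append(f"ligand-not-whitelisted ({entry.ligand_kind})")
    if nucleophile is not None:
        if entry.altloc_override:
            # manually vetted alternative conformation (transition-state
            # exception): the occupancy/ADP screen is waived
            pass
        else:
            screen = screen_nucleophile(
                nucleophile.o_nuc, thresholds.occupancy_min, thresholds.adp_max
            )
            if not screen.passed:
                reasons.append(f"disordered-nucleophile ({screen.reason})")
    if (
        geometry is not None
        and role == PRIMARY
        and entry.asparaginase_class == 1
        and geometry.d > thresholds.fge_max_d
    ):
        reasons.append(f"fge-open (d {geometry.d:.2f} > {thresholds.fge_max_d:.1f} A)")
    return FilterStatus(included=not reasons, reasons=tuple(reasons))


def _resolve_nucleophile(
    model: StructureModel, entry: ManifestEntry, address: AtomAddress, role: str
) -> NucleophileSite:
    if entry.altloc_override:
        # "prefer this conformer where one exists": candidates without any
        # altloc lettering fall back to the default policy
        try:
            atom = select_atom(
                model,
                address.residue,
                address.atom_name,
                altloc_policy="explicit",
                altloc=entry.altloc_override,
            )
        except AmbiguousAltlocError:
            atom = select_atom(model, address.residue, address.atom_name)
    else:
        atom = select_atom(model, address.residue, address.atom_name)
    return NucleophileSite(residue=address.residue, o_nuc=atom, role=role)


def analyze_case(
    entry: ManifestEntry,
    model: StructureModel,
    thresholds: Thresholds = Thresholds(),
) -> list[CaseResult]:
    """One CaseResult per nucleophile candidate of one manifest entry.

    Oxygen-role orientation by the oxyanion hole is applied before any
    geometry.  An unresolvable secondary candidate produces a warning, not a
    failure; an unresolvable ligand or primary fails the whole case.
    """
    try:
        kind = LigandKind(entry.ligand_kind)
    except ValueError:
        status = FilterStatus(False, (f"ligand-not-whitelisted ({entry.ligand_kind})",))
        return [
            CaseResult(entry, PRIMARY, None, False, status),
        ]
    site = resolve_electrophile(model, entry.ligand, kind)
    donors = tuple(
        select_atom(model, addr.residue, addr.atom_name)
        for addr in entry.oxyanion_donors
    )
    site, swap_applied = orient_by_oxyanion_hole(site, OxyanionHole(donors=donors))

    candidates: list[tuple[str, AtomAddress]] = [(PRIMARY, entry.primary_nucleophile)]
    if entry.secondary_nucleophile is not None:
        candidates.append((SECONDARY, entry.secondary_nucleophile))

    results: list[CaseResult] = []
    for role, address in candidates:
        try:
            nucleophile = _resolve_nucleophile(model, entry, address, role)
        except BurgiDunitzError as exc:
            if role == SECONDARY:
                warnings.warn(
                    f"{entry.structure_id}: secondary nucleophile {address} "
                    f"not resolvable: {exc}",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            raise
        geometry = compute_attack(site, nucleophile, thresholds.degeneracy_tol)
        status = apply_filters(entry, model, geometry, nucleophile, role, thresholds)
        results.append(
            CaseResult(
                entry=entry,
                nucleophile_role=role,
                geometry=geometry,
                swap_applied=swap_applied,
                filter_status=status,
            )
        )
    return results


def analyze_manifest(
    entries: list[ManifestEntry],
    pdb_dir: str | Path | None = None,
    thresholds: Thresholds = Thresholds(),
) -> list[CaseResult]:
    """Batch driver: per-case failures are isolated and recorded.

    Results come back in manifest order; a summary of inclusion/exclusion
    counts is logged.
    """
    results: list[CaseResult] = []
    for entry in entries:
        path = Path(entry.path)
        if pdb_dir is not None and not path.is_absolute():
            path = Path(pdb_dir) / path
        try:
            model = read_structure(path)
            results.extend(analyze_case(entry, model, thresholds))
        except (BurgiDunitzError, OSError) as exc:
            logger.warning("case %s failed: %s", entry.structure_id, exc)
            results.append(
                CaseResult(
                    entry=entry,
                    nucleophile_role=PRIMARY,
                    geometry=None,
                    swap_applied=False,
                    filter_status=FilterStatus(False, (f"error: {exc}",)),
                    error=str(exc),
                )
            )
    n_inc = sum(1 for r in results if r.filter_status.included)
    n_swap = sum(1 for r in results if r.swap_applied and r.nucleophile_role == PRIMARY)
    logger.info(
        "analyzed %d cases: %d included, %d excluded, %d oxygen swaps",
        len(results), n_inc, len(results) - n_inc, n_swap,
    )
    return results


# ---------------------------------------------------------------------------
# manifest CSV


MANIFEST_COLUMNS = [
    "structure_id", "path", "class", "subtype", "chain",
    "primary_nucleophile", "secondary_nucleophile",
    "ligand", "ligand_kind", "oxyanion_donors",
    "altloc_override", "resolution", "notes",
]


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Parse a survey manifest CSV (columns per :data:`MANIFEST_COLUMNS`)."""
    try:
        df = pd.read_csv(path, dtype=str).fillna("")
    except Exception as exc:
        raise ManifestError(f"unreadable manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "notes"]
    if missing:
        raise ManifestError(f"manifest {path} lacks columns: {missing}")
    entries: list[ManifestEntry] = []
    for _, row in df.iterrows():
        secondary = row.get("secondary_nucleophile", "")
        entries.append(
            ManifestEntry(
                structure_id=row["structure_id"],
                path=row["path"],
                asparaginase_class=int(row["class"]) if row["class"] else 0,
                subtype=row["subtype"] or "none",
                chain_id=row["chain"],
                primary_nucleophile=parse_atom_address(row["primary_nucleophile"]),
                secondary_nucleophile=(
                    parse_atom_address(secondary) if secondary else None
                ),
                ligand=parse_residue_address(row["ligand"]),
                ligand_kind=row["ligand_kind"],
                oxyanion_donors=tuple(
                    parse_atom_address(a)
                    for a in row["oxyanion_donors"].split(";")
                    if a.strip()
                ),
                altloc_override=row.get("altloc_override", ""),
                resolution=float(row["resolution"]) if row.get("resolution") else None,
                notes=row.get("notes", ""),
            )
        )
    return entries


def write_manifest(entries: list[ManifestEntry], path: str | Path) -> Path:
    rows = []
    for e in entries:
        rows.append(
            {
                "structure_id": e.structure_id,
                "path": e.path,
                "class": e.asparaginase_class or "",
                "subtype": e.subtype,
                "chain": e.chain_id,
                "primary_nucleophile": str(e.primary_nucleophile),
                "secondary_nucleophile": (
                    str(e.secondary_nucleophile) if e.secondary_nucleophile else ""
                ),
                "ligand": str(e.ligand),
                "ligand_kind": e.ligand_kind,
                "oxyanion_donors": ";".join(str(a) for a in e.oxyanion_donors),
                "altloc_override": e.altloc_override,
                "resolution": "" if e.resolution is None else f"{e.resolution:.2f}",
                "notes": e.notes,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return Path(path)
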