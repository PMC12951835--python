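"""Forward-construction of idealized active sites with prescribed geometry.

A planar (optionally pyramidalized) amide/carboxylate electrophile is laid
out in a canonical frame and a hydroxyl nucleophile is placed so that the
*analysis-side* definitions of (d, α_BD, Φ_attack) evaluate exactly to the
requested values.  The azimuth of the nucleophile on the Bürgi–Dunitz cone is
found by deterministic 1-D root bracketing against an independently written
torsion oracle, which pins the sign convention once and makes round-trip
agreement with the analyzer genuine evidence rather than a tautology: none of
the oracle functions here share code with :mod:`burgidunitz.geometry`.

Fixtures can be emitted as minimal legacy-PDB files so that the whole
pipeline — file parsing, atom selection, orientation, geometry, statistics —
is exercisable without any external structure downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.optimize import brentq

from .electrophile import ElectrophileSite, LigandKind, NucleophileSite, OxyanionHole
from .errors import ConstructionError
from .structure_io import AtomRecord, ResidueKey

# ---------------------------------------------------------------------------
# independent oracles (tests only; elementary constructions)


def oracle_angle(a: Sequence[float], b: Sequence[float], c: Sequence[float]) -> float:
    """Angle at vertex b via the normalized dot product, degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident points in oracle_angle")
    return math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(u, v)) / (nu * nv)))))


def oracle_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion via half-plane normals, acos magnitude + triple-product
    sign (right-hand convention), degrees in (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b2 = p3 - p2
    n1 = np.cross(p2 - p1, b2)
    n2 = np.cross(b2, p4 - p3)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("collinear triple in oracle_dihedral")
    cosang = float(np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    # standard convention (cis = 0, clockwise-far-bond positive viewed from
    # p2): det[n1, n2, b2] > 0 means the turn is counterclockwise, negative
    if float(np.dot(np.cross(n1, n2), b2)) > 0:
        ang = -ang
    return 180.0 if ang <= -180.0 else ang


def oracle_signed_volume(p1, p2, p3, p4) -> float:
    """Signed volume factor det[p1−p4; p2−p4; p3−p4] via a determinant, Å³."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    return float(np.linalg.det(np.stack([p1 - p4, p2 - p4, p3 - p4])))


# ---------------------------------------------------------------------------
# fixture specification and construction


@dataclass(frozen=True)
class FixtureSpec:
    """Prescription for one idealized attack.

    Amide internal geometry defaults to standard small-molecule values
    (C=O 1.23 Å, C–N 1.33 Å, C–C 1.52 Å, 120° sp² angles) but is configurable
    so non-ideal deposited geometry can be probed.
    """

    ligand_kind: LigandKind = LigandKind.L_ASN
    d: float = 2.8  # O_nuc···C_el, Å
    alpha_bd: float = 90.0  # degrees, (0, 180)
    phi_attack: float = 90.0  # degrees, (−180, 180]
    delta: float = 0.0  # pyramidalization, Å, signed toward O_nuc
    mirror: bool = False  # reflect everything through the electrophile plane
    bond_co: float = 1.23
    bond_cn: float = 1.33
    bond_cc: float = 1.52
    angle_o_n: float = 120.0  # O–C_el–N, degrees
    angle_o_c: float = 120.0  # O–C_el–C_chain, degrees
    nucleophile_resname: str = "THR"
    nucleophile_resnum: int = 12
    nucleophile_atom: str = "OG1"
    nucleophile_occupancy: float = 1.0
    nucleophile_adp: float = 20.0
    chain_id: str = "A"
    ligand_resnum: int = 900
    with_hole: bool = True
    donor_atoms: tuple[tuple[str, int, str], ...] = (
        ("THR", 12, "N"),
        ("THR", 89, "N"),
    )
    decoy_offset: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ConstructionError(f"d must be positive, got {self.d}")
        if not 0.0 < self.alpha_bd < 180.0:
            raise ConstructionError(
                f"alpha_bd must be in (0, 180), got {self.alpha_bd}"
            )


def _atom(
    name: str,
    pos: np.ndarray,
    resname: str,
    resnum: int,
    chain: str,
    element: str,
    occ: float = 1.0,
    adp: float = 15.0,
    hetero: bool = False,
) -> AtomRecord:
    return AtomRecord(
        atom_name=name,
        altloc="",
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        insertion_code="",
        position=np.asarray(pos, float),
        occupancy=occ,
        adp=adp,
        element=element,
        is_hetero=hetero,
    )


def _place_on_cone(
    c_el: np.ndarray,
    o_carbonyl: np.ndarray,
    d: float,
    alpha_bd: float,
    psi: float | np.ndarray,
) -> np.ndarray:
    """Point(s) at distance d from c_el, angle alpha_bd to the C=O bond,
    azimuth psi (scalar or array)."""
    e = o_carbonyl - c_el
    e = e / np.linalg.norm(e)
    # orthonormal completion, deterministic
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, e)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = ref - np.dot(ref, e) * e
    u = u / np.linalg.norm(u)
    w = np.cross(e, u)
    a = math.radians(alpha_bd)
    psi = np.asarray(psi, float)
    direction = (
        math.cos(a) * e
        + math.sin(a)
        * (np.cos(psi)[..., None] * u + np.sin(psi)[..., None] * w)
    )
    return c_el + d * np.squeeze(direction)


def _wrap(angle: float) -> float:
    """Wrap to (−180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a <= -180.0 else a


def _oracle_dihedral_grid(
    points: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> np.ndarray:
    """Vectorized form of :func:`oracle_dihedral` for the coarse azimuth scan
    (same acos-magnitude + triple-product-sign construction)."""
    b2 = p3 - p2
    n1 = np.cross(p2 - points, b2)
    n2 = np.cross(b2, p4 - p3)
    denom = np.linalg.norm(n1, axis=-1) * np.linalg.norm(n2)
    cosang = np.clip(n1 @ n2 / np.where(denom == 0, np.nan, denom), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    sign = np.where(np.cross(n1, n2) @ b2 > 0, -1.0, 1.0)
    ang = sign * ang
    return np.where(ang <= -180.0, 180.0, ang)


def _solve_azimuth(
    c_el: np.ndarray,
    o_carbonyl: np.ndarray,
    c_prime: np.ndarray,
    c_chain: np.ndarray,
    d: float,
    alpha_bd: float,
    phi_target: float,
) -> np.ndarray:
    """Find the cone azimuth at which the torsion O_nuc–O=C′–C equals phi_target.

    Deterministic bracketing on a coarse grid followed by Brent refinement
    against the independent torsion oracle (tolerance 1e−10°).
    """

    def residual(psi: float) -> float:
        p = _place_on_cone(c_el, o_carbonyl, d, alpha_bd, psi)
        return _wrap(oracle_dihedral(p, o_carbonyl, c_prime, c_chain) - phi_target)

    n_grid = 360
    psis = np.linspace(-math.pi, math.pi, n_grid, endpoint=False)
    grid_points = _place_on_cone(c_el, o_carbonyl, d, alpha_bd, psis)
    ang = _oracle_dihedral_grid(grid_points, o_carbonyl, c_prime, c_chain)
    if np.any(np.isnan(ang)):
        raise ConstructionError("degenerate cone for the requested spec")
    res = (ang - phi_target + 180.0) % 360.0 - 180.0
    res = np.where(res <= -180.0, 180.0, res)
    best = int(np.argmin(np.abs(res)))
    lo, hi = psis[best] - 2 * math.pi / n_grid, psis[best] + 2 * math.pi / n_grid
    r_lo, r_hi = residual(lo), residual(hi)
    # avoid the ±180° wrap discontinuity: both endpoints must be on the
    # continuous branch around the root
    if abs(r_lo) > 90 or abs(r_hi) > 90 or r_lo * r_hi > 0:
        raise ConstructionError(
            f"no azimuth bracket for phi={phi_target} (alpha_bd={alpha_bd})"
        )
    psi = brentq(residual, lo, hi, xtol=1e-13, maxiter=200)
    p = _place_on_cone(c_el, o_carbonyl, d, alpha_bd, psi)
    if abs(residual(psi)) > 1e-10:
        raise ConstructionError("azimuth solve did not converge to 1e-10 deg")
    return p


def build_site(
    spec: FixtureSpec,
) -> tuple[ElectrophileSite, NucleophileSite, OxyanionHole | None]:
    """Construct an idealized site realizing the spec exactly.

    The substituents are laid out in the z = 0 plane with the carbonyl O on
    +x; the nucleophile is placed on the Bürgi–Dunitz cone at the azimuth
    solved for Φ_attack.  Pyramidalization displaces C_el along the plane
    normal toward (Δ > 0) or away from (Δ < 0) the nucleophile, after which
    the nucleophile is re-placed so d and α_BD remain exact relative to the
    displaced center.
    """
    name_c, name_o, name_n, name_cc = spec.ligand_kind.atom_names
    o_pos = np.array([spec.bond_co, 0.0, 0.0])
    n_pos = spec.bond_cn * np.array(
        [math.cos(math.radians(spec.angle_o_n)), math.sin(math.radians(spec.angle_o_n)), 0.0]
    )
    c_pos = spec.bond_cc * np.array(
        [math.cos(math.radians(-spec.angle_o_c)), math.sin(math.radians(-spec.angle_o_c)), 0.0]
    )
    c_el = np.zeros(3)
    c_prime = np.zeros(3)  # projection of C_el on the z=0 substituent plane

    # stage 1: planar placement fixes which side of the plane the attack is on
    o_nuc = _solve_azimuth(
        c_el, o_pos, c_prime, c_pos, spec.d, spec.alpha_bd, spec.phi_attack
    )
    side = math.copysign(1.0, o_nuc[2]) if abs(o_nuc[2]) > 1e-12 else 0.0
    if spec.delta != 0.0:
        if side == 0.0:
            raise ConstructionError(
                "pyramidalization is undefined for an in-plane nucleophile"
            )
        c_el = np.array([0.0, 0.0, side * spec.delta])
        # stage 2: re-place the nucleophile relative to the displaced center
        o_nuc = _solve_azimuth(
            c_el, o_pos, c_prime, c_pos, spec.d, spec.alpha_bd, spec.phi_attack
        )

    donors: list[AtomRecord] = []
    if spec.with_hole:
        radial = (o_pos - c_prime) / np.linalg.norm(o_pos - c_prime)
        for i, (resname, resnum, atom_name) in enumerate(spec.donor_atoms):
            z_off = 0.8 if i % 2 == 0 else -0.8
            pos = o_pos + 2.9 * radial + np.array([0.0, 0.0, z_off])
            donors.append(
                _atom(atom_name, pos, resname, resnum, spec.chain_id, atom_name[0])
            )

    if spec.mirror:
        # reflection through the electrophile (z = 0) plane
        o_nuc = o_nuc * np.array([1.0, 1.0, -1.0])
        c_el = c_el * np.array([1.0, 1.0, -1.0])
        donors = [
            replace(a, position=a.position * np.array([1.0, 1.0, -1.0]))
            for a in donors
        ]

    lig_resname = spec.ligand_kind.residue_name
    site = ElectrophileSite(
        c_el=_atom(name_c, c_el, lig_resname, spec.ligand_resnum, spec.chain_id, "C", hetero=True),
        o_carbonyl=_atom(name_o, o_pos, lig_resname, spec.ligand_resnum, spec.chain_id, "O", hetero=True),
        n_amide=_atom(
            name_n, n_pos, lig_resname, spec.ligand_resnum, spec.chain_id,
            name_n[0], hetero=True,
        ),
        c_chain=_atom(name_cc, c_pos, lig_resname, spec.ligand_resnum, spec.chain_id, "C", hetero=True),
        kind=spec.ligand_kind,
    )
    nuc_key = ResidueKey(
        chain_id=spec.chain_id,
        residue_number=spec.nucleophile_resnum,
        residue_name=spec.nucleophile_resname,
    )
    nucleophile = NucleophileSite(
        residue=nuc_key,
        o_nuc=_atom(
            spec.nucleophile_atom,
            o_nuc,
            spec.nucleophile_resname,
            spec.nucleophile_resnum,
            spec.chain_id,
            "O",
            occ=spec.nucleophile_occupancy,
            adp=spec.nucleophile_adp,
        ),
        role="primary",
    )
    hole = OxyanionHole(donors=tuple(donors)) if donors else None
    return site, nucleophile, hole


def decoy_nucleophile(
    spec: FixtureSpec, primary: NucleophileSite, resnum: int = 89
) -> NucleophileSite:
    """A second (decoy) hydroxyl placed at a fixed offset from the primary."""
    if spec.decoy_offset is None:
        raise ConstructionError("spec has no decoy_offset")
    pos = primary.o_nuc.position + np.asarray(spec.decoy_offset, float)
    rec = replace(primary.o_nuc, position=pos, residue_number=resnum)
    key = ResidueKey(
        chain_id=spec.chain_id,
        residue_number=resnum,
        residue_name=spec.nucleophile_resname,
    )
    return NucleophileSite(residue=key, o_nuc=rec, role="secondary")


def swap_deposited_oxygen_names(site: ElectrophileSite) -> ElectrophileSite:
    """Exchange the deposited *names* of the two terminal oxygens.

    Positions and roles are untouched; only the labels written to a file are
    reversed.  Used to emulate depositions where the carboxylate oxygen in
    the oxyanion hole was named OD2/OE2.
    """
    if not site.kind.is_acid:
        raise ConstructionError("name swap only applies to acid ligands")
    o_name, n_name = site.o_carbonyl.atom_name, site.n_amide.atom_name
    return replace(
        site,
        o_carbonyl=replace(site.o_carbonyl, atom_name=n_name),
        n_amide=replace(site.n_amide, atom_name=o_name),
    )


# ---------------------------------------------------------------------------
# PDB emission


def _records_to_structure(
    records: Sequence[AtomRecord], structure_id: str, resolution: float | None
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure_id
    if resolution is not None:
        st.resolution = float(resolution)
    model = gemmi.Model("1")
    # gemmi containers copy on add_*, so assemble bottom-up
    by_chain: dict[str, dict[tuple, list[AtomRecord]]] = {}
    for rec in records:
        rkey = (rec.residue_number, rec.insertion_code, rec.residue_name, rec.is_hetero)
        by_chain.setdefault(rec.chain_id, {}).setdefault(rkey, []).append(rec)
    for chain_id, residues in by_chain.items():
        chain = gemmi.Chain(chain_id)
        for (num, icode, resname, hetero), recs in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(num, icode or " ")
            res.het_flag = "H" if hetero else "A"
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.atom_name
                atom.altloc = rec.altloc or "\0"
                atom.pos = gemmi.Position(*rec.position)
                atom.occ = rec.occupancy
                atom.b_iso = rec.adp
                atom.element = gemmi.Element(rec.element or rec.atom_name[0])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(
    path: str | Path,
    site: ElectrophileSite,
    nucleophiles: Sequence[NucleophileSite] = (),
    hole: OxyanionHole | None = None,
    extra_atoms: Sequence[AtomRecord] = (),
    resolution: float | None = None,
) -> Path:
    """Emit a minimal legacy-PDB file readable by :mod:`structure_io`.

    The ligand goes out as HETATM records under its deposited residue code
    (ASN/ASP/GLN/GLU/DSG/DAS); nucleophile and donor atoms as ATOM records.
    Residues are sorted by (chain, residue number) for determinism.
    """
    path = Path(path)
    records: list[AtomRecord] = [
        site.c_el, site.o_carbonyl, site.n_amide, site.c_chain,
    ]
    for nuc in nucleophiles:
        records.append(nuc.o_nuc)
    if hole is not None:
        records.extend(hole.donors)
    records.extend(extra_atoms)
    # stable order: protein residues first by number, ligand (hetero) last
    records.sort(
        key=lambda r: (r.chain_id, r.is_hetero, r.residue_number, r.atom_name, r.altloc)
    )
    st = _records_to_structure(records, path.stem, resolution)
    st.write_pdb(str(path))
    return path


def write_two_conformer_pdb(
    path: str | Path,
    occ_a: float = 0.6,
    occ_b: float = 0.4,
    offset: tuple[float, float, float] = (0.6, 0.3, 0.0),
) -> Path:
    """A nucleophile with two altloc conformers, for altloc-policy tests."""
    spec = FixtureSpec()
    site, nuc, hole = build_site(spec)
    a = replace(nuc.o_nuc, altloc="A", occupancy=occ_a)
    b = replace(
        nuc.o_nuc,
        altloc="B",
        occupancy=occ_b,
        position=nuc.o_nuc.position + np.asarray(offset),
    )
    return write_pdb(path, site, [], hole, extra_atoms=[a, b], resolution=1.5)


# ---------------------------------------------------------------------------
# spec (de)serialization for batch generation


_CSV_FIELDS = ["ligand_kind", "d", "alpha_bd", "phi_attack", "delta", "mirror"]


def specs_to_csv(specs: Sequence[FixtureSpec], path: str | Path) -> Path:
    import csv

    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for s in specs:
            writer.writerow(
                [s.ligand_kind.value, s.d, s.alpha_bd, s.phi_attack, s.delta, int(s.mirror)]
            )
    return path


def specs_from_csv(path: str | Path) -> list[FixtureSpec]:
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                FixtureSpec(
                    ligand_kind=LigandKind(row["ligand_kind"]),
                    d=float(row["d"]),
                    alpha_bd=float(row["alpha_bd"]),
                    phi_attack=float(row["phi_attack"]),
                    delta=float(row["delta"]),
                    mirror=bool(int(row["mirror"])),
                )
            )
    return out
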