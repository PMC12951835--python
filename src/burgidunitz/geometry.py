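"""Stereochemical parametrization of one nucleophile→electrophile approach.

The electrophile is a trigonal sp² carbon C_el (the side-chain amide or
carboxylate carbon of the ligand) with three substituents: the carbonyl
oxygen O, the amide nitrogen N (or the second carboxylate oxygen standing in
for it), and the chain carbon C.  The attacking hydroxyl oxygen O_nuc of a
Ser/Thr side chain approaches this plane.  The parameters computed here:

``d``        O_nuc···C_el distance, Å.
``alpha_bd`` Bürgi–Dunitz angle O_nuc–C_el=O, degrees in [0, 180].
``alpha_fl`` Flippin–Lodge angle, 180° − ∠(P, C′, O), where P is the
             projection of O_nuc and C′ the projection of C_el onto the
             substituent (electrophile) plane.  Signed: positive when P lies
             on the amide-nitrogen side of the O=C′ line.  Indeterminate
             (None) when the in-plane offset dP = |P − C′| is below a
             tolerance — a perpendicular attack has no azimuth.
``alpha_lw`` angle between C_el→O_nuc and its projection onto plane Ω (the
             plane through the C=O bond perpendicular to the electrophile
             plane).  Signed: positive on the amide-nitrogen side of Ω.
``phi_attack`` standard right-hand torsion O_nuc–O=C′–C, degrees in
             (−180, 180].  Its sign encodes the attacked face: Φ > 0 is a
             pro-S attack, Φ < 0 pro-R.
``tau``      acute dihedral between the electrophile plane and the
             O_nuc/C_el/O plane, degrees in [0, 90].  On a planar site the
             identity sin α_LW = sin α_BD · cos τ holds exactly.
``delta``    pyramidalization: distance of C_el from its substituent plane,
             positive toward O_nuc.
``chirality`` R/S letter of the incipient tetrahedral center, from the signed
             volume of the four substituents in CIP priority order
             O_nuc > O_carbonyl > N_amide > C_chain.

All angle conventions were fixed once against independent constructions (see
the test-suite oracles); in particular the Φ-sign/chirality correspondence is
intrinsic to the right-hand torsion and CIP order, not an added constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import DegenerateGeometryError

if TYPE_CHECKING:  # pragma: no cover
    from .electrophile import ElectrophileSite, NucleophileSite

#: below this in-plane offset dP (Å) the Flippin–Lodge azimuth is reported
#: indeterminate instead of numerically noisy
DEFAULT_DEGENERACY_TOL = 0.05

#: below this |signed volume| (Å³) the four substituents are treated as
#: coplanar and no chirality letter is assigned
CHIRAL_VOLUME_TOL = 0.01

INDETERMINATE = "indeterminate"

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class Plane:
    """A plane through ``anchor`` with unit ``normal``."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise DegenerateGeometryError("zero-length plane normal")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))

    def signed_distance(self, point: np.ndarray) -> float:
        return float(np.dot(np.asarray(point, float) - self.anchor, self.normal))


@dataclass(frozen=True)
class AttackGeometry:
    """Full parameter vector of one nucleophilic approach."""

    d: float
    dp: float
    alpha_bd: float
    alpha_fl: float | None  # None == indeterminate (perpendicular attack)
    alpha_lw: float
    phi_attack: float
    tau: float
    delta: float
    chirality: str  # "S" | "R" | "indeterminate"
    chiral_volume: float


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _COLLINEAR_TOL:
        raise DegenerateGeometryError(f"degenerate {what} (zero length)")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Planar angle at vertex ``b``, degrees in [0, 180]."""
    u = _unit(np.asarray(a, float) - np.asarray(b, float), "angle arm")
    v = _unit(np.asarray(c, float) - np.asarray(b, float), "angle arm")
    # atan2 form is stable near 0 and 180 where acos loses precision
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def dihedral_deg(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Standard signed torsion of the ordered quadruple, degrees in (−180, 180].

    Standard convention: looking from p2 toward p3, the angle is positive
    when the far bond p3–p4 is rotated clockwise relative to the near bond
    p1–p2 (cis = 0°).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear triple in torsion")
    m = np.cross(n1, _unit(b2, "torsion axis"))
    ang = float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))
    return 180.0 if ang <= -180.0 else ang


def substituent_plane(site: "ElectrophileSite") -> Plane:
    """Exact plane through the three substituents of C_el.

    The normal's sign is an internal convention (right-hand order
    O → N → C); every signed parameter downstream is defined relative to
    named atoms, never to this sign.
    """
    o = site.o_carbonyl.position
    n = site.n_amide.position
    c = site.c_chain.position
    normal = np.cross(n - o, c - o)
    if np.linalg.norm(normal) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear electrophile substituents")
    return Plane(anchor=o, normal=normal)


def project_onto_plane(point: np.ndarray, plane: Plane) -> np.ndarray:
    """Orthogonal projection (foot of perpendicular) of ``point`` onto ``plane``."""
    point = np.asarray(point, float)
    return point - plane.signed_distance(point) * plane.normal


def pyramidalization(site: "ElectrophileSite", o_nuc: np.ndarray) -> float:
    """Signed out-of-plane displacement Δ of C_el, positive toward O_nuc."""
    plane = substituent_plane(site)
    h_el = plane.signed_distance(site.c_el.position)
    h_nuc = plane.signed_distance(np.asarray(o_nuc, float))
    sign = 1.0 if h_el * h_nuc >= 0 else -1.0
    return sign * abs(h_el)


def bd_angle(o_nuc: np.ndarray, c_el: np.ndarray, o_carbonyl: np.ndarray) -> float:
    """Bürgi–Dunitz angle O_nuc–C_el=O, degrees in [0, 180]."""
    return angle_deg(o_nuc, c_el, o_carbonyl)


def _c_prime(site: "ElectrophileSite", plane: Plane) -> np.ndarray:
    return project_onto_plane(site.c_el.position, plane)


def fl_angle(
    site: "ElectrophileSite",
    o_nuc: np.ndarray,
    degeneracy_tol: float = DEFAULT_DEGENERACY_TOL,
) -> tuple[float | None, float]:
    """Flippin–Lodge azimuth and the in-plane offset dP.

    Returns ``(alpha_fl, dp)``; ``alpha_fl`` is None when dP < tolerance
    (the attack is perpendicular and has no defined azimuth).  The magnitude
    is 180° − ∠(P, C′, O); the sign is positive when P lies on the
    amide-nitrogen half-plane of the line through C′ and O.
    """
    plane = substituent_plane(site)
    c_prime = _c_prime(site, plane)
    p = project_onto_plane(np.asarray(o_nuc, float), plane)
    dp = float(np.linalg.norm(p - c_prime))
    if dp < degeneracy_tol:
        return None, dp
    magnitude = 180.0 - angle_deg(p, c_prime, site.o_carbonyl.position)
    # in-plane perpendicular (toward the N side) to the C'→O line
    e_co = _unit(site.o_carbonyl.position - c_prime, "C'=O direction")
    n_vec = site.n_amide.position - c_prime
    n_perp = n_vec - np.dot(n_vec, e_co) * e_co
    n_perp = _unit(n_perp, "in-plane N direction")
    side = float(np.dot(p - c_prime, n_perp))
    sign = 1.0 if side >= 0 else -1.0
    return sign * magnitude, dp


def lw_angle(site: "ElectrophileSite", o_nuc: np.ndarray) -> float:
    """Out-of-Ω-plane deviation of the approach vector, signed, degrees.

    Ω is the plane through C_el and the C=O bond, perpendicular to the
    electrophile plane.  The angle is between C_el→O_nuc and its projection
    P′ onto Ω; positive when O_nuc lies on the chain-carbon side of Ω
    (i.e. away from the amide nitrogen).  This sign choice is a convention
    constant, calibrated once so that survey group means carry the
    field's customary signs; for a planar site it makes
    α_LW ≈ arcsin(sin α_BD · cos Φ) hold with matching signs.
    """
    plane = substituent_plane(site)
    c_el = site.c_el.position
    e_co = _unit(site.o_carbonyl.position - c_el, "C=O bond")
    n_omega = np.cross(e_co, plane.normal)
    if np.linalg.norm(n_omega) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("C=O bond parallel to plane normal")
    n_omega = _unit(n_omega)
    # orient away from the amide-nitrogen side (sign calibration)
    if np.dot(site.n_amide.position - c_el, n_omega) > 0:
        n_omega = -n_omega
    v = _unit(np.asarray(o_nuc, float) - c_el, "approach vector")
    sin_lw = float(np.clip(np.dot(v, n_omega), -1.0, 1.0))
    return float(np.degrees(np.arcsin(sin_lw)))


def phi_attack(site: "ElectrophileSite", o_nuc: np.ndarray) -> float:
    """Attack torsion Φ: O_nuc–O=C′–C, signed, degrees in (−180, 180].

    C′ is the projection of C_el onto the substituent plane, so the torsion
    axis is the carbonyl bond direction as seen in the plane even for a
    pyramidalized center.  Φ > 0 is the pro-S face.
    """
    plane = substituent_plane(site)
    return dihedral_deg(
        np.asarray(o_nuc, float),
        site.o_carbonyl.position,
        _c_prime(site, plane),
        site.c_chain.position,
    )


def tau_dihedral(site: "ElectrophileSite", o_nuc: np.ndarray) -> float:
    """Acute dihedral τ between the electrophile plane and the O_nuc/C_el/O
    plane, degrees in [0, 90]."""
    plane = substituent_plane(site)
    c_el = site.c_el.position
    v_o = site.o_carbonyl.position - c_el
    v_n = np.asarray(o_nuc, float) - c_el
    n_attack = np.cross(v_o, v_n)
    if np.linalg.norm(n_attack) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("O_nuc collinear with the C=O bond")
    n_attack = _unit(n_attack)
    cos_t = abs(float(np.dot(n_attack, plane.normal)))
    ang = float(np.degrees(np.arctan2(np.sqrt(max(0.0, 1.0 - cos_t**2)), cos_t)))
    return min(ang, 180.0 - ang) if ang > 90.0 else ang


def chirality(
    site: "ElectrophileSite",
    o_nuc: np.ndarray,
    volume_tol: float = CHIRAL_VOLUME_TOL,
) -> tuple[str, float]:
    """R/S letter and signed chiral volume of the incipient tetrahedral center.

    O_nuc is taken as the fourth substituent of C_el.  The volume is the
    scalar triple product of the vectors from the chain carbon (lowest CIP
    priority) to O_nuc, O_carbonyl and N_amide, in descending CIP priority;
    positive volume is S.  Coplanar substituents (|V| < tolerance) give
    ``indeterminate`` rather than an error.
    """
    d = site.c_chain.position
    vol = float(
        np.dot(
            np.asarray(o_nuc, float) - d,
            np.cross(site.o_carbonyl.position - d, site.n_amide.position - d),
        )
    )
    if abs(vol) < volume_tol:
        return INDETERMINATE, vol
    return ("S" if vol > 0 else "R"), vol


def compute_attack(
    site: "ElectrophileSite",
    nucleophile: "NucleophileSite",
    degeneracy_tol: float = DEFAULT_DEGENERACY_TOL,
) -> AttackGeometry:
    """Aggregate the full parameter vector for one attack."""
    o_nuc = nucleophile.o_nuc.position
    c_el = site.c_el.position
    d = float(np.linalg.norm(o_nuc - c_el))
    if d < _COLLINEAR_TOL:
        raise DegenerateGeometryError("nucleophile coincides with C_el")
    alpha_fl, dp = fl_angle(site, o_nuc, degeneracy_tol)
    letter, volume = chirality(site, o_nuc)
    return AttackGeometry(
        d=d,
        dp=dp,
        alpha_bd=bd_angle(o_nuc, c_el, site.o_carbonyl.position),
        alpha_fl=alpha_fl,
        alpha_lw=lw_angle(site, o_nuc),
        phi_attack=phi_attack(site, o_nuc),
        tau=tau_dihedral(site, o_nuc),
        delta=pyramidalization(site, o_nuc),
        chirality=letter,
        chiral_volume=volume,
    )
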