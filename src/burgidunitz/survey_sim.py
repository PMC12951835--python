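"""Synthetic survey corpus emulating the curated asparaginase study set.

The generator's defaults are the study conditions: the per-group case counts
(14 class 1 type I, 128 type II including 4 covalent transition states,
9 type s, 9 class 2, 8 class 3), the per-group normal distributions of α_BD
and Φ_attack, exactly 100 aspartate complexes deposited with their terminal
oxygens named the wrong way round, a few D-enantiomer ligand outliers, and a
couple of deliberately non-compliant entries (low resolution, open gating
loop) that the curation filters must reject.

Every case is written as a minimal legacy-PDB file plus a manifest row, so a
run of the generator followed by :func:`burgidunitz.pipeline.analyze_manifest`
exercises the complete tool path: file parsing → atom selection → oxygen
orientation → geometry → curation → statistics.

What this corpus emulates: the group structure, parameter distributions,
deposition errors and curation triggers of the real survey.  What it does
not: real protein scaffolds, crystallographic noise correlated with
resolution, or restraint-idealized internal ligand geometry — group-level
statistics are meaningful here, per-case realism is not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .electrophile import LigandKind
from .fixtures import FixtureSpec, build_site, swap_deposited_oxygen_names, write_pdb
from .pipeline import AtomAddress, ManifestEntry, write_manifest
from .structure_io import ResidueKey


@dataclass(frozen=True)
class GroupCondition:
    """Sampling conditions for one survey group."""

    label: str
    asparaginase_class: int
    subtype: str
    n: int
    alpha_bd: tuple[float, float]  # mean, sigma (degrees)
    phi: tuple[float, float]  # mean, sigma (degrees)
    d_dist: tuple[str, float, float] = ("norm", 2.9, 0.25)  # kind, a, b
    n_asp: int = 0  # how many cases carry the Asp product ligand
    n_swapped: int = 0  # of those, how many are deposited with O names reversed
    nucleophile: tuple[str, int, str] = ("THR", 12, "OG1")
    secondary: tuple[str, int, str] = ("THR", 89, "OG1")
    donors: tuple[tuple[str, int, str], ...] = (("THR", 12, "N"), ("THR", 89, "N"))
    ligand_kind: LigandKind = LigandKind.L_ASN
    mirror: bool = False
    transition_state: bool = False  # altloc-pinned covalent TS conformer
    resolution: tuple[float, float] = (1.2, 2.6)  # uniform range
    open_fge_d: float | None = None  # force the primary this far away


#: the survey's group structure (class 2 d range as printed; class 3 split
#: into six metal-anchored cases near 90° and two wobbly metal-free cases
#: near 110°, whose pooled mean/σ reproduce the class 3 row)
DEFAULT_GROUPS: tuple[GroupCondition, ...] = (
    GroupCondition("c1_t1", 1, "I", 14, (87.0, 6.7), (92.3, 4.0),
                   n_asp=8, n_swapped=6),
    GroupCondition("c1_t2", 1, "II", 124, (90.1, 6.1), (89.2, 6.3),
                   n_asp=100, n_swapped=82),
    GroupCondition("c1_t2_ts", 1, "II", 4, (110.0, 2.0), (89.2, 6.3),
                   d_dist=("norm", 1.5, 0.05), transition_state=True),
    GroupCondition("c1_ts", 1, "s", 9, (87.7, 4.9), (82.4, 4.2),
                   n_asp=4, n_swapped=3,
                   nucleophile=("THR", 16, "OG1"), secondary=("THR", 87, "OG1"),
                   donors=(("THR", 16, "N"), ("THR", 87, "N"))),
    GroupCondition("c2", 2, "none", 9, (73.7, 15.0), (-83.5, 13.4),
                   d_dist=("uniform", 2.52, 3.89), n_asp=5, n_swapped=4,
                   nucleophile=("THR", 179, "OG1"), secondary=("THR", 230, "OG1"),
                   donors=(("GLY", 231, "N"),)),
    GroupCondition("c3", 3, "none", 6, (88.2, 2.0), (90.2, 3.0),
                   n_asp=5, n_swapped=5,
                   nucleophile=("SER", 48, "OG"), secondary=("SER", 80, "OG"),
                   donors=(("SER", 48, "N"), ("ALA", 266, "N"))),
    GroupCondition("c3_metalfree", 3, "none", 2, (88.2, 2.0), (110.0, 3.0),
                   nucleophile=("SER", 48, "OG"), secondary=("SER", 80, "OG"),
                   donors=(("SER", 48, "N"), ("ALA", 266, "N"))),
)

#: entries the curation filters must reject (plus D-ligand outliers that stay
#: in the per-case table but outside the substrate-complex statistics)
EXTRA_GROUPS: tuple[GroupCondition, ...] = (
    GroupCondition("c1_t2_dlig", 1, "II", 3, (90.1, 6.1), (89.2, 6.3),
                   ligand_kind=LigandKind.D_ASN, mirror=True),
    GroupCondition("c1_t2_lowres", 1, "II", 1, (90.1, 6.1), (89.2, 6.3),
                   resolution=(3.4, 3.4)),
    GroupCondition("c1_t2_open", 1, "II", 1, (90.1, 6.1), (89.2, 6.3),
                   open_fge_d=10.5),
)

_SECONDARY_D = (4.3, 0.3)  # non-productive alternative candidate: far ...
_SECONDARY_BD = (120.0, 10.0)  # ... and off the perpendicular approach


def _stratified_uniforms(rng: np.random.Generator, n: int) -> np.ndarray:
    """Latin-hypercube quantiles: one jittered draw per stratum, shuffled.

    A group of 8–14 cases drawn iid from N(μ, σ) can easily land an
    unrepresentative sample; stratifying the quantiles keeps each small
    synthetic group representative of its nominal distribution while every
    value still follows it.
    """
    u = (np.arange(n) + rng.uniform(size=n)) / n
    rng.shuffle(u)
    return u


def _stratified_normal(
    rng: np.random.Generator, mean: float, sigma: float, n: int
) -> np.ndarray:
    return mean + sigma * norm.ppf(_stratified_uniforms(rng, n))


def _sample_d_array(
    rng: np.random.Generator, dist: tuple[str, float, float], n: int
) -> np.ndarray:
    kind, a, b = dist
    if kind == "uniform":
        return a + (b - a) * _stratified_uniforms(rng, n)
    return np.clip(_stratified_normal(rng, a, b, n), 1.2, 3.95)


def _wrap_phi(phi: float) -> float:
    a = (phi + 180.0) % 360.0 - 180.0
    return 180.0 if a <= -180.0 else a


def generate_survey(
    out_dir: str | Path,
    seed: int = 0,
    groups: tuple[GroupCondition, ...] = DEFAULT_GROUPS + EXTRA_GROUPS,
) -> Path:
    """Write the synthetic corpus (PDB files + manifest CSV) to ``out_dir``.

    Deterministic for a fixed seed.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []
    for group in groups:
        alphas = np.clip(
            _stratified_normal(rng, *group.alpha_bd, group.n), 20.0, 165.0
        )
        phis = _stratified_normal(rng, *group.phi, group.n)
        ds = _sample_d_array(rng, group.d_dist, group.n)
        for i in range(group.n):
            structure_id = f"{group.label}_{i:03d}"
            is_asp = i < group.n_asp
            is_swapped = i < group.n_swapped
            if group.ligand_kind is LigandKind.L_ASN and is_asp:
                kind = LigandKind.L_ASP
            else:
                kind = group.ligand_kind

            alpha = float(alphas[i])
            phi = _wrap_phi(float(phis[i]))
            if group.mirror:
                phi = -phi
            d = float(ds[i])
            if group.open_fge_d is not None:
                d = group.open_fge_d
            delta = float(rng.uniform(0.1, 0.3)) if group.transition_state else 0.0

            nuc_name, nuc_num, nuc_atom = group.nucleophile
            sec_name, sec_num, sec_atom = group.secondary
            spec = FixtureSpec(
                ligand_kind=kind,
                d=d,
                alpha_bd=alpha,
                phi_attack=phi,
                delta=delta,
                nucleophile_resname=nuc_name,
                nucleophile_resnum=nuc_num,
                nucleophile_atom=nuc_atom,
                donor_atoms=group.donors,
            )
            site, nuc1, hole = build_site(spec)

            sec_spec = replace(
                spec,
                d=float(np.clip(rng.normal(*_SECONDARY_D), 3.2, 5.5)),
                alpha_bd=float(np.clip(rng.normal(*_SECONDARY_BD), 60.0, 165.0)),
                phi_attack=_wrap_phi(rng.uniform(-175.0, 175.0)),
                delta=0.0,
                nucleophile_resname=sec_name,
                nucleophile_resnum=sec_num,
                nucleophile_atom=sec_atom,
                with_hole=False,
            )
            _, nuc2, _ = build_site(sec_spec)
            nuc2 = replace(nuc2, role="secondary")

            file_site = swap_deposited_oxygen_names(site) if is_swapped else site
            resolution = float(rng.uniform(*group.resolution))
            extra = []
            nucleophiles = [nuc1, nuc2]
            altloc_override = ""
            if group.transition_state:
                # the TS conformer is an alternative at half occupancy; the
                # manifest pins it explicitly
                a_rec = replace(nuc1.o_nuc, altloc="A", occupancy=0.5)
                b_rec = replace(
                    nuc1.o_nuc,
                    altloc="B",
                    occupancy=0.5,
                    position=nuc1.o_nuc.position + np.array([1.4, 0.9, 0.6]),
                )
                extra = [a_rec, b_rec]
                nucleophiles = [nuc2]
                altloc_override = "A"

            path = out_dir / f"{structure_id}.pdb"
            write_pdb(path, file_site, nucleophiles, hole,
                      extra_atoms=extra, resolution=resolution)
            entries.append(
                ManifestEntry(
                    structure_id=structure_id,
                    path=path.name,
                    asparaginase_class=group.asparaginase_class,
                    subtype=group.subtype,
                    chain_id="A",
                    primary_nucleophile=AtomAddress(
                        ResidueKey("A", nuc_num, residue_name=nuc_name), nuc_atom
                    ),
                    secondary_nucleophile=AtomAddress(
                        ResidueKey("A", sec_num, residue_name=sec_name), sec_atom
                    ),
                    ligand=ResidueKey(
                        "A", spec.ligand_resnum, residue_name=kind.residue_name
                    ),
                    ligand_kind=kind.value,
                    oxyanion_donors=tuple(
                        AtomAddress(ResidueKey("A", num, residue_name=name), atom)
                        for name, num, atom in group.donors
                    ),
                    altloc_override=altloc_override,
                    resolution=resolution,
                    notes=group.label,
                )
            )
    return write_manifest(entries, out_dir / "manifest.csv")
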