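"""Shared fixtures and independent helpers for the test suite.

``make_site`` builds electrophile frames from hand-placed coordinates so that
geometry unit tests do not depend on the synthetic-fixture generator; the
generator-vs-analyzer round trips live in the property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from burgidunitz.electrophile import (
    ElectrophileSite,
    LigandKind,
    NucleophileSite,
    OxyanionHole,
)
from burgidunitz.structure_io import AtomRecord, ResidueKey


def make_atom(
    name: str,
    pos,
    resname: str = "ASN",
    resnum: int = 900,
    chain: str = "A",
    occ: float = 1.0,
    adp: float = 20.0,
    altloc: str = "",
    hetero: bool = True,
) -> AtomRecord:
    return AtomRecord(
        atom_name=name,
        altloc=altloc,
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        insertion_code="",
        position=np.asarray(pos, float),
        occupancy=occ,
        adp=adp,
        element=name[0],
        is_hetero=hetero,
    )


# canonical hand-placed amide frame: C_el at the origin, carbonyl O on +x,
# amide N at +120 deg, chain C at -120 deg, all in the z=0 plane
CANONICAL = {
    "CG": np.array([0.0, 0.0, 0.0]),
    "OD1": np.array([1.23, 0.0, 0.0]),
    "ND2": 1.33 * np.array([np.cos(np.radians(120)), np.sin(np.radians(120)), 0.0]),
    "CB": 1.52 * np.array([np.cos(np.radians(-120)), np.sin(np.radians(-120)), 0.0]),
}


def make_site(
    c_el=None, o_c=None, n_a=None, c_c=None, kind: LigandKind = LigandKind.L_ASN
) -> ElectrophileSite:
    names = kind.atom_names
    resname = kind.residue_name
    return ElectrophileSite(
        c_el=make_atom(names[0], CANONICAL["CG"] if c_el is None else c_el, resname),
        o_carbonyl=make_atom(names[1], CANONICAL["OD1"] if o_c is None else o_c, resname),
        n_amide=make_atom(names[2], CANONICAL["ND2"] if n_a is None else n_a, resname),
        c_chain=make_atom(names[3], CANONICAL["CB"] if c_c is None else c_c, resname),
        kind=kind,
    )


def make_nucleophile(pos, resnum: int = 12, role: str = "primary") -> NucleophileSite:
    rec = make_atom("OG1", pos, resname="THR", resnum=resnum, hetero=False)
    return NucleophileSite(
        residue=ResidueKey("A", resnum, residue_name="THR"), o_nuc=rec, role=role
    )


def make_hole(*positions) -> OxyanionHole:
    donors = tuple(
        make_atom("N", p, resname="GLY", resnum=200 + i, hetero=False)
        for i, p in enumerate(positions)
    )
    return OxyanionHole(donors=donors)


def rigid_transform(rng: np.random.Generator):
    """A random proper rotation + translation (seeded)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return q, t


def transform_site(site: ElectrophileSite, q: np.ndarray, t: np.ndarray):
    from dataclasses import replace

    def move(a: AtomRecord) -> AtomRecord:
        return replace(a, position=q @ a.position + t)

    return replace(
        site,
        c_el=move(site.c_el),
        o_carbonyl=move(site.o_carbonyl),
        n_amide=move(site.n_amide),
        c_chain=move(site.c_chain),
    )


@pytest.fixture
def canonical_site() -> ElectrophileSite:
    return make_site()


@pytest.fixture(scope="session")
def survey_dir(tmp_path_factory):
    """The full synthetic survey corpus, generated once per session."""
    from burgidunitz.survey_sim import generate_survey

    out = tmp_path_factory.mktemp("survey")
    manifest = generate_survey(out, seed=20260926 % 2**31)
    return out, manifest


@pytest.fixture(scope="session")
def survey_results(survey_dir):
    import warnings

    from burgidunitz.pipeline import analyze_manifest, read_manifest

    out, manifest = survey_dir
    entries = read_manifest(manifest)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = analyze_manifest(entries, pdb_dir=out)
    return results
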