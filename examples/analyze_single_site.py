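"""Parametrize one nucleophilic attack from a coordinate file.

Builds a small idealized active site (an asparagine side-chain amide with a
threonine hydroxyl poised 2.9 Å from the amide carbon), writes it as a
legacy-PDB file, reads it back and computes the full attack parameter vector.
"""

import tempfile
from pathlib import Path

from burgidunitz import (
    FixtureSpec,
    LigandKind,
    OxyanionHole,
    build_site,
    compute_attack,
    read_structure,
    resolve_electrophile,
    select_atom,
    write_pdb,
)
from burgidunitz.pipeline import parse_atom_address

with tempfile.TemporaryDirectory() as tmp:
    spec = FixtureSpec(d=2.9, alpha_bd=92.0, phi_attack=88.0)
    site, nucleophile, hole = build_site(spec)
    path = write_pdb(Path(tmp) / "site.pdb", site, [nucleophile], hole,
                     resolution=1.6)

    model = read_structure(path)
    ligand_key = site.c_el.residue_key
    site = resolve_electrophile(model, ligand_key, LigandKind.L_ASN)
    o_nuc = select_atom(model, parse_atom_address("A/THR/12/OG1").residue, "OG1")

    from burgidunitz import NucleophileSite
    geometry = compute_attack(site, NucleophileSite(o_nuc.residue_key, o_nuc))

print(f"d        = {geometry.d:7.3f} A   (nucleophile-to-carbon distance)")
print(f"alpha_BD = {geometry.alpha_bd:7.2f} deg (approach angle to the C=O bond)")
print(f"alpha_FL = {geometry.alpha_fl:7.2f} deg (in-plane azimuth of the approach)")
print(f"alpha_LW = {geometry.alpha_lw:7.2f} deg (deviation from the Omega plane)")
print(f"Phi      = {geometry.phi_attack:7.2f} deg (attack torsion; >0 means pro-S)")
print(f"tau      = {geometry.tau:7.2f} deg (tilt of the attack plane)")
print(f"delta    = {geometry.delta:7.3f} A   (pyramidalization toward the nucleophile)")
print(f"chirality: {geometry.chirality} (of the incipient tetrahedral center)")
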