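"""Repair a reversed carboxylate-oxygen assignment using the oxyanion hole.

An aspartate product ligand has two chemically equivalent terminal oxygens;
depositions frequently name them the wrong way round.  Atom roles are first
assigned by deposited name (OD1 = carbonyl role), then the oxygen actually
sitting in the oxyanion hole — the backbone N-H donors that stabilize the
developing negative charge — is moved into the carbonyl role by mean donor
distance, and the swap is recorded.
"""

import tempfile
from pathlib import Path

from burgidunitz import (
    FixtureSpec,
    LigandKind,
    OxyanionHole,
    build_site,
    orient_by_oxyanion_hole,
    read_structure,
    resolve_electrophile,
    screen_nucleophile,
    select_atom,
    write_pdb,
)
from burgidunitz.fixtures import swap_deposited_oxygen_names

spec = FixtureSpec(ligand_kind=LigandKind.L_ASP, d=2.85, alpha_bd=90.0,
                   phi_attack=90.0)
site, nucleophile, hole = build_site(spec)

with tempfile.TemporaryDirectory() as tmp:
    # write the file the way a flawed deposition would: names reversed
    path = write_pdb(Path(tmp) / "flawed.pdb",
                     swap_deposited_oxygen_names(site), [nucleophile], hole)
    model = read_structure(path)
    deposited = resolve_electrophile(model, site.c_el.residue_key,
                                     LigandKind.L_ASP)
    donors = tuple(select_atom(model, d.residue_key, "N")
                   for d in hole.donors)
    read_hole = OxyanionHole(donors=donors)

for atom in (deposited.o_carbonyl, deposited.n_amide):
    dist = read_hole.mean_distance(atom.position)
    print(f"deposited {atom.atom_name} ({'carbonyl' if atom is deposited.o_carbonyl else 'amide-N'} "
          f"role): mean donor distance {dist:.2f} A")

oriented, swap_applied = orient_by_oxyanion_hole(deposited, read_hole)
print(f"swap applied: {swap_applied}; carbonyl role now held by "
      f"{oriented.o_carbonyl.atom_name}")

again, swapped_again = orient_by_oxyanion_hole(oriented, read_hole)
print(f"re-orienting is a no-op: swap applied again = {swapped_again}")

# the order screen that gates survey inclusion
screen = screen_nucleophile(nucleophile.o_nuc)
print(f"nucleophile screen (occupancy {nucleophile.o_nuc.occupancy:.2f}, "
      f"B {nucleophile.o_nuc.adp:.0f} A^2): "
      f"{'pass' if screen.passed else 'fail: ' + screen.reason}")
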