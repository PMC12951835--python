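"""Run the full survey pipeline over the synthetic corpus.

Generates ~170 minimal active-site structures emulating the three enzyme
classes (plus deliberately flawed depositions: reversed carboxylate oxygen
names, a low-resolution entry, an open gating loop, D-enantiomer ligands),
analyzes them through the curation pipeline and prints the per-group
statistics.  Counts and the oxygen-swap tally are exact corpus structure;
the means are sample statistics of the generated distributions.
"""

import logging
import tempfile
import warnings

from burgidunitz import analyze_manifest, class_table, generate_survey, read_manifest
from burgidunitz.stats import results_to_frame

logging.basicConfig(level=logging.INFO)

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_survey(tmp, seed=1)
    entries = read_manifest(manifest)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = analyze_manifest(entries, pdb_dir=tmp)

frame = results_to_frame(results)
primary = frame[frame["role"] == "primary"]
print(f"\ncases: {len(entries)}, oxygen-name swaps repaired: "
      f"{int(primary['swap_applied'].sum())}")
print("excluded primaries:",
      primary.loc[~primary["included"], "exclude_reasons"].tolist())
print(f"\n{'group':<22}{'n':>4}  {'alpha_BD':>12}  {'Phi_attack':>12}")
for gs in class_table(results):
    print(f"{gs.label:<22}{gs.n:>4}  {gs.formatted('alpha_bd'):>12}  "
          f"{gs.formatted('phi_attack'):>12}")
print("\nA positive group-mean Phi means the class attacks the pro-S face of "
      "the amide;\nclass 2 (negative Phi) attacks from the opposite, pro-R side.")
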