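# Methods

## The model

The package treats a nucleophilic addition to a trigonal sp² carbon as a
geometric object: four ligand atoms (the electrophilic carbon C_el and its
substituents — carbonyl oxygen O, amide nitrogen N or a second carboxylate
oxygen in its role, chain carbon C) plus the attacking hydroxyl oxygen O_nuc
of a Ser/Thr side chain.  The *electrophile plane* is the exact plane through
the three substituents, never a least-squares fit — with three points the
plane is determined, and a pyramidalized C_el must not drag the reference
plane with it.  All distances are in Å, all angles in degrees, and all
computations run in the orthogonal coordinate frame of the input file; no
symmetry expansion is performed and only the first model of a multi-model
file is read (the intended corpus is crystallographic).

### Parameter definitions and conventions

* **d** = |O_nuc − C_el|.
* **α_BD** = planar angle O_nuc–C_el=O in [0°, 180°], computed with the
  atan2 form (stable near 0° and 180°).
* **C′** is the orthogonal projection of C_el onto the electrophile plane;
  **P** the projection of O_nuc.  **dP** = |P − C′| is the in-plane offset of
  the attack.
* **α_FL** = 180° − ∠(P, C′, O), signed positive when P lies on the
  amide-nitrogen half-plane of the O=C′ line.  When dP < 0.05 Å the azimuth
  of a (near-)perpendicular attack is numerically meaningless and α_FL is
  reported *indeterminate* rather than noisy.  The 0.05 Å tolerance is a
  package choice: at dP = 0.05 Å a 0.001 Å coordinate perturbation (the
  precision of the PDB format) already moves α_FL by about a degree.
* **Ω** is the plane through C_el and the C=O bond perpendicular to the
  electrophile plane.  **α_LW** = angle between C_el→O_nuc and its projection
  onto Ω, i.e. arcsin of the out-of-Ω component.  Sign convention: positive
  when O_nuc lies on the chain-carbon side of Ω (away from the amide
  nitrogen).  The sign is a convention constant calibrated once so that
  survey group means carry the customary signs; on a planar site it makes
  α_LW = arcsin(sin α_BD · cos Φ) with matching signs.  (The opposite,
  toward-nitrogen choice flips every class 1/2 group mean sign.)
* **Φ_attack** = the standard signed torsion of the ordered quadruple
  (O_nuc, O, C′, C), reported in (−180°, 180°] with no folding or
  normalization.  Using C′ rather than C_el keeps the torsion axis in the
  electrophile plane even for a pyramidalized center.
* **τ** = acute dihedral in [0°, 90°] between the electrophile plane and the
  plane through O_nuc, C_el and O.  The acute convention makes the identity
  sin α_LW = sin α_BD · cos τ sign-free.
* **Δ** = distance of C_el from the electrophile plane, signed positive when
  C_el and O_nuc are on the same side.  Because the sign is defined relative
  to the nucleophile, Δ is invariant under reflection of the whole site
  through the electrophile plane — as are α_LW and α_FL, whose signs are
  in-plane properties.  Reflection negates exactly Φ_attack and flips the
  chirality letter; d, α_BD, dP and τ are preserved.  These invariants are
  property-tested.
* **Chirality**: O_nuc is taken as the fourth substituent of C_el, giving
  CIP priorities O_nuc > O_carbonyl > N_amide > C_chain (the nucleophile
  oxygen carries two carbon neighbours, the oxyanion oxygen only one).  The
  signed volume is the scalar triple product of the vectors from the chain
  carbon to the other three substituents in priority order; positive volume
  is S.  The letter always agrees with the Φ sign rule (Φ > 0 ⇔ S) — with
  the standard torsion and CIP order this is a theorem, not an added
  constant, and the test suite checks it on every fixture.  Below
  |V| = 0.01 Å³ the substituents are effectively coplanar and the letter is
  *indeterminate*.

### Oxygen-role orientation

For carboxylate ligands (Asp/Glu) the two terminal oxygens are chemically
equivalent and deposition names are unreliable.  The package assigns the
carbonyl role to whichever oxygen has the smaller *mean Euclidean distance*
to the oxyanion-hole donor atoms supplied per case (1–3 main-chain N or
side-chain O atoms).  Mean donor distance is robust for small donor counts
and needs no hydrogen placement; a per-donor contact beyond 3.5 Å is logged
as strained but not rejected, since some deposited geometries genuinely are.
For amide ligands (Asn/Gln) nothing is moved, but a warning is raised if the
amide nitrogen sits in the hole — a deposition error worth flagging.  The
orientation step is idempotent and depends only on geometry, never on the
deposited names.

### Curation rules

A case is excluded (with accumulated, machine-readable reasons) when any of
the following fails; defaults sit on `Thresholds` and are CLI-overridable:

* resolution ≤ 3.0 Å (beyond that, restraints dominate the geometry);
* nucleophile order screen: occupancy ≥ 1.0 and B-factor strictly < 100 Å².
  The screen is waived when the manifest pins an explicit altloc — that is
  how the manually vetted half-occupancy transition-state conformers enter
  the analysis;
* for the class 1 *primary* candidate only, d ≤ 4.0 Å: the primary Thr of
  this class rides a mobile gating loop, and an open loop parks it far from
  the ligand in a non-productive pose.  Secondary candidates are never
  distance-filtered, so the alternative nucleophile of an open-loop case
  still contributes;
* ligand kind within {L-ASN, L-ASP, L-GLN, L-GLU, D-ASN, D-ASP}.

The manifest is the single source of residue numbering per homolog (e.g. the
class 1 candidate pair is Thr12/Thr89 in one reference enzyme but
Thr16/Thr87 in the short-chain relatives); no sequence alignment is
attempted.  Isomorphous duplicate depositions are retained — they carry
independent experimental observations.

### Statistics

Group statistics are the arithmetic mean with the sample (n−1) standard
deviation, printed μ (σ), σ omitted for n = 1.  Indeterminate α_FL values are
dropped from the α_FL aggregate and counted.  α_FL is averaged linearly over
signed values, not circularly: its full-range scatter for near-perpendicular
attacks *is* the finding (the parameter carries little information there),
and circular averaging would hide it.  The pooled all-classes row takes the
Φ mean over |Φ| — classes attack both faces of the amide and signed means
would cancel.  Outlier flagging: D-enantiomer ligands by kind; otherwise
|Φ − μ| > kσ (default k = 3) against group statistics computed from the
natural-substrate cases only.  Histograms use fixed-width zero-aligned bins,
5° for angles and 0.1 Å for d by default.

## The synthetic corpus

`survey_sim.generate_survey` emits a complete survey — minimal PDB files plus
a manifest — whose defaults are the study conditions of the asparaginase
survey: group sizes 14 (class 1 type I), 128 (type II, of which 4 are
covalent transition-state conformers pinned by altloc at d ≈ 1.5 Å and
α_BD ≈ 110°), 9 (type s), 9 (class 2) and 8 (class 3, of which 2 emulate
metal-free complexes with wobbly substrates at Φ ≈ 110°); per-group normal
distributions of α_BD and Φ (class 1 near 90°/+90°, class 2 at
74°/−83.5°, class 3 at 88°/+95°); exactly 100 carboxylate cases written with
their oxygen names reversed; 3 D-enantiomer outliers; and one
low-resolution plus one open-loop entry that the filters must reject.
Class 2 attack distances are drawn uniformly on the observed 2.52–3.89 Å
range; class 1/3 from N(2.9, 0.25) Å truncated to a physically sensible
window (no d statistics are published for those classes; 2.9 Å is a typical
pre-reaction O⋯C contact).  Secondary candidates are placed deliberately
non-productively (d ≈ 4.3 Å, α_BD ≈ 120°, uniform Φ).

Group parameters are drawn by Latin-hypercube (stratified inverse-CDF)
sampling: at n = 8–14 an iid normal draw is often unrepresentative of its own
nominal mean, which would make downstream comparisons measure sampling luck
rather than the pipeline.  Each value still follows the stated distribution;
the stratification only guarantees the small group represents it.

What the corpus emulates: the group structure, the parameter distributions,
the deposition errors the orientation step must repair, and every curation
trigger.  What it does not: real protein scaffolds, resolution-correlated
coordinate noise, restraint-idealized internal ligand geometry, or any
correlation between d and the angular parameters.  Green survey tests
therefore demonstrate that the pipeline recovers whatever structure a corpus
contains — not that real depositions are this clean.  The α_FL scatter, the
α_LW–(α_BD, Φ) coupling and the Φ-sign/chirality correspondence are emergent
in the corpus rather than sampled, which is deliberate: they probe the
analysis, not the generator.

## Numerical choices

* Fixture construction solves the cone azimuth of the nucleophile against an
  independently written torsion oracle: a 1° coarse scan brackets the root,
  Brent refinement (xtol 10⁻¹³ rad) polishes it, and the solve aborts if the
  residual exceeds 10⁻¹⁰ degrees.  The generator and the analyzer share no
  geometry code, so their agreement (round-trip error ~10⁻¹³ over a 500-point
  grid) is evidence, not tautology.
* Pyramidalized fixtures displace C_el along the plane normal *after* a first
  planar solve fixes the attack side, then re-solve the azimuth so d and
  α_BD stay exact relative to the displaced center.
* Altloc selection defaults to highest occupancy with ties broken by altloc
  identifier, making selection deterministic; an explicit policy addresses a
  named conformer and errors on ambiguity.  A manifest altloc override means
  "prefer this conformer where one exists": atoms without altloc lettering
  fall back to the default policy, so a pinned primary does not break an
  un-lettered secondary in the same entry.
* Angles are computed with atan2 formulations throughout; collinear or
  coincident inputs raise a degenerate-geometry error rather than returning
  NaN, except chirality, where coplanarity is a legitimate in-plane geometry
  and yields *indeterminate*.
* The whole pipeline is deterministic: re-running a survey byte-identically
  reproduces its CSV outputs.

## Problem sizes

The test suite and the acceptance script run the geometry grid at 500
fixtures (5 × 5 × 20 over d ∈ [2.0, 4.0] Å, α_BD ∈ [60°, 120°],
Φ ∈ (−180°, 180°]) and the survey at the full 173-entry corpus (346 candidate
analyses); both complete in seconds.  These sizes are the package's chosen
reference configuration, matching the survey's own scale.

## Known limitations

* α_FL and α_LW sign conventions are package choices (the quantities'
  original descriptions leave them open); comparisons with other software
  should check signs on a known case first.  Published class 3 α_LW values
  are not reproducible from ideal-planar geometry under any single sign
  convention — real depositions deviate from the ideal α_LW–(α_BD, Φ)
  coupling at small n.
* The oxyanion-hole criterion is purely geometric (mean donor distance); no
  hydrogens are placed and no hydrogen-bond energetics are modeled.
* Only legacy PDB is read.  mmCIF would be a small extension through the
  same gemmi backend but is outside the current surface.
* Quality metadata (resolution aside) comes from the manifest, not from
  validation reports; the package does not judge electron density.
* No automatic discovery of complexes: the manifest is curated by the user,
  as the survey's corpus was.
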