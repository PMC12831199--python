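# Methods

## Scope and model

`slimscan` implements a structure-aware short-linear-motif search as a
five-stage funnel over a proteome of predicted models, followed by
complex-evidence ranking.  The motif model is a fixed-width (5),
position-specific allowed-residue set with positions labelled −2…+2
(acidic/serine position 0, tyrosine +2).  Matching is exact set
membership; `X` (unknown residue) matches no position.  All overlapping
occurrences are reported; funnel counting is protein-level (a protein
with several occurrences counts once), which is the quantity the
stage-wise counts refer to.

## Secondary-structure assignment

Stage 2 and the in-complex helicity check use a compact Kabsch–Sander
(DSSP-style) assigner written for this package:

* Backbone amide hydrogens are reconstructed at 1.01 Å from N, anti to
  the preceding carbonyl C→O direction; prolines, chain-initial residues
  and residues following a chain break get none.
* The electrostatic hydrogen-bond energy is
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, clamped
  at −9.9; a bond is accepted iff `E < −0.5` kcal/mol, with a minimum
  donor/acceptor separation of two positions in chain order.
* n-turns (n = 3, 4, 5) arise from an accepted bond NH(i+n)→CO(i) with
  an unbroken span; two consecutive n-turns make a helix (all three
  helix types map to `H`).  Parallel/antiparallel bridge patterns mark
  both partners `E` (isolated bridges included, since `B` simplifies to
  `E`).  Everything else — including what an 8-class assigner would call
  turns and bends — is loop `C`, consistent with a filter alphabet of
  "helical or loop".
* Chain breaks are declared at consecutive Cα–Cα distances > 4.5 Å.
  Turn patterns may not span a break; long-range bridges between the
  fragments remain legal (as between separate strands).
* A Cα–Cα pre-filter at 9 Å skips pairs that cannot achieve an accepted
  bond (the O···N distance of any accepted bond is far below that).

The published search used a molecular-viewer annotation whose algorithm
is not public; this assigner is a documented, reproducible stand-in that
agrees with it on regular elements by construction.  The method tag
(`ks-hbond/3-class (turns+bends→C)`) is recorded in outputs.  On real
proteomes a few borderline assignments may differ from other assigners,
shifting stage-2 counts by small amounts; the stage-1 count is
assigner-independent.

The stage-2 rule is: discard a motif if **any** of its five residues is
labelled `E`; helical, loop and mixed helix/loop contexts all pass.
Motifs whose window cannot be annotated (missing backbone) are excluded
with reason "unannotated".

## Complex evidence

Candidate complexes are consumed as prediction bundles
(`model.pdb`/`model.cif`, `pae.json`, `summary.json` with an `iptm`
field); the package never runs structure prediction.

* **Groove contact**: any heavy-atom pair between the five motif
  residues and the hydrophobic patch (full-length Spa2 numbering 48,
  51, 59, 98, 101, 109) within 4.5 Å.  The cutoffs (4.5 Å contacts,
  3.5 Å O···O hydrogen bonds) are standard structural-biology
  conventions; the source study states none, so both are configurable
  in `GrooveDefinition`, as is a numbering offset for SHD1 fragment
  constructs.
* **Helicity in complex**: ≥ 4 of the 5 motif residues labelled `H` by
  the assigner run on the whole complex.
* **Orientation**: distance from the Tyr(+2) hydroxyl oxygen to the
  nearest carboxylate oxygen of Asp112 vs Asp62; the closer one within
  3.5 Å decides canonical vs flipped, neither within cutoff is
  indeterminate, and a non-tyrosine +2 is "not applicable" (a distinct
  outcome).  Orientation is only evaluated for motifs in groove
  contact.
* **Interface PAE**: PAE matrices are asymmetric, so the mean (and min)
  are taken over both off-diagonal motif×receptor blocks and averaged.
  Two JSON dialects are read: a square `predicted_aligned_error`
  list-of-lists and paired 1-based `residue1/residue2/distance` arrays;
  the chain boundary comes from metadata or an explicit argument.

All geometric quantities depend only on inter-atomic distances, hence
are rigid-motion invariant (verified to 1e-6 Å in tests).

## Funnel semantics

Stage 3 consumes a user-supplied two-column TSV (id, comma-separated
compartment labels; `cytosol`/`cytoplasm` count as cytosolic by
default).  No annotation database is hard-wired.  Proteins absent from
the table are kept and flagged `unknown-localization` by default
(strict mode drops them): the published counts span stages 3–4 jointly
and cannot disambiguate strictness, so the permissive reading is the
default.

Stage 5 keeps candidates with `ipTM ≥ reference` — inclusive, so the
reference candidate always survives itself.  The reference score is
given directly or resolved from the reference candidate's bundle.

Stages 3–5 are optional; a disabled stage copies survivors forward and
is marked `skipped` in the report.  Reports (JSON/TSV) carry per-stage
survivor sets, per-candidate exclusion stages and reasons, a
configuration echo, and an `experimental_validation: pending` column
standing in for the experimental sixth stage.  Funnel monotonicity
(non-increasing counts, nested id sets) is asserted on every run.

## Synthetic data generator

The generator emulates the four input families so the funnel can be
validated offline with exact truth.  Everything is a pure function of
(parameters, seed); identical calls write byte-identical files.

* **Backbones** are built by NeRF extension from ideal covalent
  geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°), with
  the carbonyl O in the peptide plane and Cβ by tetrahedral
  construction.  Dihedral presets: helix (−57°, −47°) — giving the
  canonical 3.80 Å Cα–Cα spacing and i→i+4 hydrogen bonds — and strand
  (−139°, 135°).  Coil is sampled per residue from φ ∈ (−100°, −70°),
  ψ ∈ (10°, 60°), a window away from the helix, strand and
  polyproline-II basins, so coil stretches assign `C`.
* **Strand context** requires a bridge partner (a lone extended strand
  correctly labels `C`), so strand-planted motifs sit on the first
  strand of an antiparallel hairpin closed by a two-residue turn with
  dihedrals (0°, 90°), (90°, 0°), chosen during design because the two
  strands then register into clean bridge patterns.
* **Toy proteomes** plant motifs (residues drawn from the pattern) at
  seeded positions in helix/strand/coil context; sequences are
  rejection-sampled to avoid accidental pattern hits, and any survivor
  of the retry budget is recorded in the truth table.  A construction
  check re-runs the assigner on every written protein and fails loudly
  if a planted context did not realise its intended filter outcome.
* **The mock receptor** is a deterministic five-helix arrangement in a
  single chain with full-length Spa2 numbering, two "wall" helices
  7.5 Å either side of a groove axis, leucines at the patch positions,
  lysine 97 and aspartates 62/112 facing the groove.  Side chains
  beyond Cβ are idealised "stubs" with correct atom names (sufficient
  for heavy-atom contacts and the Tyr-OH/Asp-carboxylate test); the
  tyrosine ring is collapsed onto its para axis, preserving the
  Cβ→OH reach.
* **Complex bundles** dock the motif helix by a deterministic
  rigid-body grid search (36 rolls × small translations) constrained to
  put the Tyr(+2) hydroxyl within hydrogen-bond distance of the target
  aspartate (D112 canonical, D62 flipped — the flipped pose also
  reverses the helix direction) while minimising wall clashes.  A
  single closed-form placement was rejected during design: anchoring
  the rigid ideal helix directly on the H-bond pushes its body into the
  opposite wall.  Non-binders violate exactly one criterion: separated
  chains (100 Å translation), an extended non-helical ligand, or
  ipTM below the reference.  PAE matrices are truncated normals —
  within-chain mean 2 Å; cross-chain mean 4.5 Å (docked) or 24 Å
  (undocked) — and ipTM is drawn above (binders), below (stage-5
  failures) or exactly at (reference analog) the 0.60 reference.
* **The funnel benchmark** (28 proteins) contains 3 strand-context
  candidates, 3 non-cytosolic, 4 stage-4 failures (two separated, two
  extended), 3 stage-5 failures, 4 binders (one flipped), the
  reference analog (serine at position 0, ipTM exactly at threshold)
  and 10 motif-free background proteins.

What passing on this generator shows — and does not show: the pipeline
logic, geometry and threshold semantics are exactly right on noise-free,
idealised inputs with planted truth.  The generator does not emulate
real side-chain packing, loop irregularity, prediction confidence
calibration, or borderline secondary structure, so agreement with
counts from a real proteome additionally depends on the assigner's
behaviour on borderline real conformations.

## Numerical choices and degenerate inputs

* Problem sizes: the benchmark proteome is 28 proteins of 70–110
  residues with 12 complex bundles (receptor 118 + ligand 21 residues);
  oracle-agreement checks use 1000 random sequences and 25–30 random
  chains of ≤ 30 residues.  These sizes make the whole validation run
  in seconds while exercising every code path.
* Energies are clamped at −9.9 kcal/mol for near-clashing geometries
  (inter-atom distance < 0.5 Å).
* Chains shorter than three residues are all-coil; five-residue windows
  that cross a numbering gap are treated as unannotated.
* PDB/mmCIF I/O is delegated to gemmi; only blank/'A' altlocs and the
  first model of multi-model files are kept, waters are dropped, MSE
  maps to M and other non-standard residues to X.
* Proteome iteration is lexicographic by entry name, so runs are
  deterministic; unparseable entries are logged and skipped, with
  "no files" and "all entries failed" distinguished as errors.

## Known limitations

* The 3-class assigner is a stand-in for the (unpublished) annotation
  used in the original search; small stage-2 count differences on real
  data are expected and surface as per-protein diffs in the report.
* Stub side chains make absolute contact distances in synthetic
  complexes approximate (closest pairs ≈ 2 Å); contact *booleans* and
  orientation calls, which is what the funnel consumes, are robust.
* The localization filter is only as good as the supplied table; the
  package ships no annotation database.
* ipTM/PAE are consumed, never computed; ranking quality inherits the
  upstream predictor's calibration.
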