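# Methods

## The system and the model

Cardiac ATTR fibrils are cross-β amyloid stacks in which each rung
("layer", equivalently "chain" in per-chain energies) carries two
proteolytic fragments of mature transthyretin at a 1:1 ratio — an
N-terminal fragment around residues 11–35 and a C-terminal fragment
starting between residues 57 and 68 depending on the polymorph. The four
polymorphs handled here differ in the conformation of a short C-terminal
segment (the "gate", around Leu58–Gly67) that closes, extends, loses, or
truncates the wall of a polar channel: the closed, open, absent and
broken gate folds. All four share a common core, Leu12–Lys35 plus
Gly67–Val122, which is the default correspondence set for structural
comparison. Residue numbering is the mature-transthyretin convention
(1–127) taken verbatim from coordinate files; nothing is renumbered.

## Helical geometry

Consecutive layers are related by a screw operator: rotation by the twist
θ (degrees per subunit, negative = left-handed, the default handedness
of these fibrils) about the helical axis plus a translation by the rise
*h* (Å) along it. The crossover distance, the quantity measured directly
on micrographs, is c = (180/|θ|)·h, reported to the nearest Å because
that is the precision at which crossovers are read from images. An
(effectively) untwisted stack, |θ| < 0.01°, has no finite crossover and
is reported as such rather than with a huge number.

The axis convention is the z-axis through the centroid of the reference
layer's Cα atoms — the standard orientation of deposited fibril models.
`expand_symmetry` applies the operator k times to produce layer k;
`estimate_helical_parameters` inverts it by superposing each consecutive
layer pair (Kabsch), orienting the rotation axis to +z, and reading the
signed rotation angle and the axial translation component; the mean over
pairs is returned with its standard deviation as a dispersion estimate.
On noise-free synthetic stacks the round trip is exact to ~1e-8; with
0.2 Å coordinate noise the dispersion is a realistic error bar
(~0.02° / ~0.005 Å on the default layer).

Note the published parameter triples are not exactly self-consistent
(e.g. twist −1.26°, rise 4.81 Å gives 687 Å while the printed crossover
is 689 Å): printed twists are rounded. The relation is implemented
exactly and the triples are never forced to agree.

## Stabilization energy

The stabilization energy estimates how much solvation free energy a chain
gains by sitting inside the fibril stack. For atom i with per-class
atomic solvation parameter σ_i (cal·mol⁻¹·Å⁻²):

    e_i = σ_i · (A_i(in stack) − A_i(reference))  [converted to kcal/mol]

so that burying apolar carbon (σ > 0) is stabilizing (negative) and
burying charged nitrogen (σ < 0) is destabilizing. Per-residue and
per-chain energies are plain sums; additivity is exact and asserted.
"Per chain" means one layer including both fragments.

Choices a user should know:

- **SASA**: Shrake–Rupley with a 1.4 Å probe and 960 deterministic
  Fibonacci-lattice points per atom by default (both configurable). The
  one-atom case equals the closed form 4π(r+probe)² exactly; clusters are
  verified in tests against an independent latitude-band quadrature at
  0.1 Å resolution (≤2%) and against biotite's implementation.
- **Radii**: a united-atom element table (C 1.90, N 1.70, O 1.40, S 1.80 Å)
  loaded from YAML config, never hard-coded; hydrogens are not modelled
  (cryo-EM models at these resolutions carry none) and their volume is
  absorbed by the radii.
- **ASP set**: the five-class Eisenberg–McLachlan parameters
  (C +16, neutral N/O −6, charged O⁻ −24, charged N⁺ −50, S +21
  cal·mol⁻¹·Å⁻²) from a YAML config with a provenance string. Charged
  classes are assigned from residue/atom names (Asp/Glu carboxylate O and
  OXT → O⁻; Lys Nζ and Arg guanidinium N → N⁺); His is treated neutral
  and fragment N-termini are not protonated, since the termini here are
  proteolytic and their state is unknown.
- **Reference state**: ISOLATED_CHAIN by default — the scored layer alone
  in the same conformation, so ΔA measures inter-chain burial only. A
  FULLY_EXTENDED option approximates an unfolded reference by scoring
  each atom in a residue-local context (own residue plus peptide-bonded
  neighbour backbone). The literature the ASP values come from used an
  unfolded reference, but the convention used for published fibril
  energies is not stated anywhere we can check offline, so both are
  exposed and the choice is always recorded in the profile's context
  metadata rather than silently assumed.
- **Stack context**: the central chain of a 5-layer stack (an odd stack
  is always built so the scored chain is central). On fixtures the
  central-chain energy changes by <1% from 5 to 7 layers, which is the
  convergence criterion that motivated the default.

The cohort comparison (fibrils vs the broader amyloid-structure
compilation) uses a two-sided Mann–Whitney U test: exact enumeration when
n₁·n₂ ≤ 10⁴ with no ties, the tie-corrected normal approximation
otherwise, with the box-plot summary (median, quartiles, whisker
extremes) per group. The shipped snapshot table is a **synthetic
stand-in** (7 fibril chains spanning −70.2…−55.4 kcal/mol against 86
cohort structures drawn once from a broader, less stable distribution);
it exercises the statistics and file contract, and a regenerated table of
real per-structure energies can be substituted via the same TSV schema.

## Polymorph comparison

Superposition is classical Kabsch least squares (proper rotations only;
reflections are never returned; collinear inputs are rejected as
ill-conditioned). `fold_rmsd` makes **one** fit on the chosen fit set —
all residues shared by both models, or the common core — across a chosen
number of consecutive layers (default 3, which is sensitive to
layer-tilt differences between polymorphs; single-layer mode available),
then reports the overall r.m.s.d. over the fitted atoms and per-residue
Cα distances for *all* shared residues under that single fit. Gate
deviations can therefore legitimately exceed the overall r.m.s.d. by an
order of magnitude. Correspondence is strictly by residue number (same
protein; no alignment needed). Which fit set and how many layers
produced a given number is carried in the profile metadata, because
published r.m.s.d. values rarely state either.

## Filament tracing

Refinement keeps only well-defined segments, so class labels cover
filaments incompletely. Segments are grouped into filaments by
(micrograph, helical tube id) when tube bookkeeping exists, else by
single-linkage proximity chaining within a pixel threshold (suggested:
1.5× the inter-box distance), ordered along the filament by projection
onto the principal axis of the segment cloud (adequate for the gently
curved filaments this targets; a strongly U-shaped filament would need a
curve-following order). A filament is *mixed* iff labelled segments of
two or more distinct classes occur on it — no minimum run length, so the
call matches the binary co-occurrence claim and nothing stronger. The
mixed fraction is computed over filaments with at least one label and is
exact under full coverage and a lower bound under partial coverage; the
summary object carries this caveat explicitly so downstream reports
cannot drop it.

## Synthetic data

The generator exists so every stage runs and is testable offline, with
known ground truth; it emulates structure, not biology:

- **Layers**: a self-avoiding 2D Cα trace (turtle instructions, 3.8 Å
  steps, ≥3.5 Å clearance between non-adjacent residues) in the z = 0
  plane, idealized β-meander strands, backbone N/C/O placed by in-plane
  ideal geometry and Cβ alternating above/below the plane. The default
  ATTR-like layer has fragments 11–35 and 57–124 with the gate at
  residues 58–62. Gate conformations modify only the gate: closed =
  pentagon-like closure (72° turns), open = extended into a free pocket,
  absent = residues removed, broken = start truncated; all non-gate
  residues keep identical coordinates across states, which is what makes
  core-vs-gate deviation tests sharp. Layers are backbone-level by
  design — side-chain packing is irrelevant to testing the scoring
  plumbing, and real depositions supply full atoms.
- **Fibrils**: layer × screw operator, optional i.i.d. Gaussian noise
  after expansion, deterministic under a seed.
- **Particle tables**: filaments as smooth, slightly curved paths inside
  a 4096-px micrograph; per-filament composition pure-1 / pure-2 / mixed
  (0.4/0.3/0.3 by default) with a per-segment Markov switch probability
  of 0.2 in mixed filaments; a configurable fraction of segments dropped
  to emulate refinement attrition. Ground truth (true composition and
  coverage per filament) is returned alongside.

What passing tests on this data do **not** show: that real fibril
energies land in any particular range (synthetic layers lack side
chains), or that proximity chaining resolves crossing filaments in
crowded micrographs. They do show the operators, estimators, summations
and bookkeeping are correct, the estimators recover generator parameters,
and the mixed-fraction estimator is a lower bound exactly when it claims
to be.

## Numerical and interface choices

- Quadrature points are deterministic; no randomness anywhere except the
  explicitly seeded noise and particle generators, so fixed seeds give
  byte-identical STAR output and identical pipeline reports.
- Chain mapping of deposited entries (chain id → layer, fragment) is
  inferred by default — fragment from the chain's starting residue
  (≥45 → C-fragment), layer from the mean axial coordinate rank — because
  chain-naming conventions vary between depositions; an explicit YAML
  mapping overrides inference, and unmapped chains fail loudly by name.
- PDB output refuses >99,999 atoms and points to mmCIF. Coordinates
  round-trip to 1e-3 Å in PDB (format precision) and ~1e-7 in mmCIF.
- Highest-occupancy conformers only; hydrogens dropped on read.
- Problem sizes in tests (3–7 layers, 93-residue layers, 120–960
  quadrature points, 100–400 synthetic filaments) were chosen as the
  smallest at which each property is cleanly exhibited.

## Known limitations

- The energy model is a buried-area × parameter surface term: no
  electrostatics beyond the charge classes, no entropy, no waters.
- The helical estimator assumes a z-aligned fibril and matched atom sets
  between layers; pseudo-2₁ screw symmetry is not modelled.
- Per-residue comparison requires identical residue numbering (true for
  one protein's polymorphs, not for cross-protein comparisons).
- The shipped cohort snapshot is synthetic (see above); conclusions about
  real cohorts require substituting real per-structure energies.
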