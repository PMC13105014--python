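# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `crossbeta`.

## Helical symmetry and cross-over algebra

A fibril's deposited helical symmetry is a screw operation: rotation by a
twist Δφ (degrees, signed) about the growth axis plus a rise Δz (Å) per
repeat.  Two-protofilament fibrils fall into three classes:

* **C₂** — subunits related by an exact 2-fold about the growth axis; the
  repeat is one molecular layer per subunit (Δφ a few degrees, Δz ≈ 4.7 Å).
* **pseudo-2₁** — a single-start helix whose consecutive molecules alternate
  between the two subunits; Δφ ≈ ±180°, Δz ≈ 2.35 Å (half the cross-β
  stacking distance).
* **C₁** — conformationally inequivalent subunits; here the repeat is taken
  as two layers (two molecules, Δz ≈ 9.4 Å), matching how such repeats are
  refined when an intensity modulation doubles the apparent repeat.

The apparent morphology depends only on the net cross-section rotation, so
`fold_twist` reduces Δφ modulo 180° into (−90°, +90°]; the cross-over
distance is `d = Δz·180°/|fold(Δφ)|` (Å → nm).  `fold(Δφ) = 0` is the
untwisted state, represented as an infinite cross-over rather than an error,
because apparently untwisted fibrils are a real observation.  Full precision
is reported alongside a nearest-integer-nm value because structure tables
print integers.

**Sign conventions.**  The deposited twist sign is stored verbatim but never
interpreted as handedness: depositions list right-handed fibrils with both
signs, so the sign encodes a refinement convention, not chirality.  All
morphology math uses |fold(Δφ)|.  When twist is *fitted from coordinates*
the package orients the axis so the rise is positive; the fitted sign is
then a genuine geometric chirality indicator (mirroring a model flips it),
but the `handedness` field stays "undetermined" because map-model
handedness assignment is out of scope.  Fitted pseudo-2₁ twists are
reported as `fold − 180°` (fold ≤ 0) or `fold + 180°` (fold > 0); this can
differ from a deposition's convention by 360°, which `fold_twist` makes
comparable.

`symmetry_operators` returns cumulative operators S⁰…S^(k−1) (plus the
2-fold mate for C₂, and the even/odd single-helix images for pseudo-2₁),
each carrying an unwrapped rotation angle so compositions report cumulative
rotation (two −181.75° steps give −363.5°/4.68 Å).

## Twist-strain model

Cross-β structures stack molecules at b = 0.48 ± 0.01 nm along the growth
axis.  A cross-over distance d forces a rotation ρ = bπ/d between
successive molecules; a rigid ordered segment of extended length L centred
on the axis then has its ends displaced transversely by L·sin(ρ/2) relative
to the molecule above, giving end spacings

    s = sqrt(b² + L² sin²(ρ/2))   (nm).

`end_spacing` evaluates this; `max_ordered_length` inverts it in L,
formalising the constraint that spacings too far above b cannot sustain
stable backbone hydrogen bonds and therefore bound the twist rate available
to a long ordered core.  b defaults to 0.48 nm and is a parameter so the
±0.01 nm tolerance can be swept.

**Measurement convention for L.**  When L is taken from a model it is the
Cα–Cα distance between the first and last conformationally ordered residues
(e.g. 7.3 nm for an ordered span of residues 14–40 in a slowly twisting
polymorph; 5.3 nm for 17–37 in a rapidly twisting one).  Published
statements of L do not specify path length versus end-to-end distance;
end-to-end of the ordered span is the declared operational choice.

## Model organisation and helical fitting

Nothing is assumed about deposited coordinate frames; the growth axis is
always estimated.  All chain pairs that superpose well (least-squares rigid
superposition on atoms matched by residue number + atom name) contribute
their rotation axes — screw mates (~180°), same-subunit stacking neighbours
(a few degrees), and C₂ mates all rotate about the growth axis — and the
axes are averaged.  Subunits are connected components of the "related by a
small (<90°) rotation" graph; layers order chains by axial centroid within
each subunit.  The pair-quality threshold is adaptive
(max(1.0 Å, 2× best pair RMSD)), which tolerates coordinate noise up to
σ ≈ 0.5 Å.

Per-layer twist and rise come from the screw decomposition of
successive-layer transforms, averaged over layer pairs and bundle members.
Symmetry classification: subunits whose single-chain superposition RMSD
exceeds 1.5 Å (configurable) are inequivalent → C₁; otherwise a ~180°
inter-subunit rotation with axial offset < 0.25·rise is C₂, and one at
half-rise offset is pseudo-2₁.  The 1.5 Å default separates "nearly
identical to within refinement precision" (bundle spread ≈ 0.3–0.7 Å) from
genuine conformational inequivalence (several Å).

Superposition is delegated to scipy's Kabsch implementation
(`Rotation.align_vectors`); tests validate it against an independently
coded Horn quaternion oracle, and dihedrals against gemmi's four-point
evaluation.  Author residue numbering (1–40 for Aβ40) is canonical and
never remapped, because every residue-level statement in the field (L17,
D23, K28, G33, …) uses it.

## Conformational annotation

**Torsions** are standard φ/ψ dihedrals in (−180°, 180°], undefined (NaN,
never 0) at chain ends or where backbone atoms are missing.  Bundle
statistics use circular means and circular SDs.

**Hydrogen bonds.**  Deposited fibril models typically contain only
non-hydrogen atoms, and no hydrogen-bond criterion accompanies the β-strand
rule in the literature; the package's default is geometric — donor N to
acceptor O ≤ 3.5 Å and N–H···O angle ≥ 120°, with the amide H taken from
the file when present or placed 1.0 Å from N opposite the C(prev)/CA
bisector when absent.  A DSSP-style electrostatic criterion
(E < −0.5 kcal/mol) is available as `mode="dssp"`.  Both cutoffs are
configurable; the defaults are assumptions to be validated against
deposited models, not published choices.

**β-strand segments.**  A strand is a maximal run of ≥3 consecutive
residues whose amide donates and whose carbonyl accepts an inter-chain bond
on one consistent axial side, with consecutive residues alternating sides —
the geometric content of "hydrogen bonds to neighbouring chains on
alternating sides", since cross-β carbonyls alternate up/down the axis.
The side label of a bond is the sign of the partner chain's axial offset.
For bundles and the several chains of one subunit, reported segments are
the majority-vote consensus across (model, chain) observations; only
interior layers vote, because the first and last layers of any finite stack
lack a neighbour on one side and cannot satisfy the rule for half their
residues.

**Deviation windows** are boundary-inclusive (φ = −160.0° does not deviate
from −130° ± 30°) and use circular distance so values near ±180° are
handled correctly.

**Axes.**  The major molecular axis runs from the N-terminal to the
C-terminal Cα of the ordered range.  Tilt (to the cross-section plane) is
averaged per chain — averaging direction vectors across helically rotated
copies first would bias the angle upward.  The herringbone angle pairs the
two subunits' chains layer by layer for the same reason, and is folded into
[0°, 90°].

**Contacts.**  Inter-subunit residue pairs by minimum sidechain heavy-atom
distance, default cutoff 5.0 Å; classified salt-bridge (acidic O / basic N
≤ 4.0 Å), hydrophobic (both residues in {A,V,L,I,M,F,W,P}; glycine has no
sidechain atoms and is excluded), else polar.  The D23–K28 salt bridge is
intra-chain Lys-NZ to Asp-OD minimum distance, bundle-averaged, present at
≤ 4.0 Å — comfortably containing the ~3.3–3.5 Å distances typical of
stable bridges.

## Comparison

Superposition RMSD takes independent fit and scoring ranges because
published figure captions sometimes align one range and score another.
Atoms are matched by residue number and atom name; mismatched residue
types are reported and scored on their common atoms, with a coverage
fraction in the report.  For bundles the default compares first members,
with an all-pairs average as an option, since published single-molecule
comparisons do not specify the bundle member.  Torsion differences are
circular, with a 10⁻³ degree floor on the significance threshold so
zero-SD self-comparisons do not flag floating-point residue.

## Synthetic generator

The generator emulates what the analyses measure, not all-atom chemistry:

* a planar 40-residue U-shaped Cα template (turn at residues 23–29 facing
  the axis, the two-fold axis between the turns of the two subunits),
  replicated by the exact screw operators of the requested symmetry;
* backbone N/C placed along the trace with a small alternating axial pleat
  (±0.3 Å) so dihedrals are well-defined;
* designed strand residues receive carbonyl O exactly 3.0 Å from the amide
  N of the *symmetry-generated* neighbour layer on alternating axial sides,
  plus an explicit amide H pointing at the O it donates to.  Phantom
  neighbours are used at stack edges, so every chain is an exact screw
  image of the template — this is what lets the fitting stage recover
  twist/rise to 10⁻⁶ on noise-free output and makes PDB output
  byte-reproducible given a seed;
* sidechains are reduced to Cβ markers plus explicit D23
  carboxylate/K28 amino atoms at a configurable separation (default 3.3 Å)
  for salt-bridge analysis;
* optional subunit tilt (rotation about the in-plane axis perpendicular to
  the end-to-end vector, so the stated tilt *is* the major-axis tilt),
  Gaussian coordinate noise from a single seeded generator, and C₁ mode
  with a second, conformationally perturbed template.

What the generator does **not** emulate: realistic sidechain packing and
rotamers (inter-subunit contact maps of default synthetic fibrils are
sparse), solvent, density maps, and the conformational accommodation by
which real strands keep hydrogen bonds under twist strain (designed bonds
are placed exactly, so strand recovery at zero noise tests the annotation
logic, not hydrogen-bond energetics).  Passing synthetic tests therefore
demonstrates correctness of the geometry and annotation pipeline, not
fidelity to any particular deposition; deposited-model checks live in a
separate, cache-gated test group.

**Width profiles** project atoms onto a plane containing the growth axis,
bin the transverse extent axially (default bin ≈ one layer), and detect
local minima with sub-bin parabolic refinement; the mean minima spacing is
the measured cross-over.  A flat profile (span < 5% of the width) is
classified untwisted.  The default is a single fixed viewing azimuth; an
optional fan average over a configurable spread (default 20°) emulates the
limited orientation spread inside one 2D class — averaging the full 180°
would cancel the modulation entirely, because the twist itself sweeps all
azimuths along z.

## Problem sizes and tolerances

The test suite generates fibrils of 3–5 layers per subunit (6–10 chains,
~200 atoms per chain) for fitting and annotation checks, and single-subunit
stacks of up to ~560 layers for width-profile checks out to 150 nm
cross-overs; these sizes make every property cheap to verify while leaving
all algorithms independent of scale.  Key tolerances: twist/rise recovery
10⁻⁶ (noise-free), cross-over round trips through coordinates 1%, width
profile minima 5%, superposition vs quaternion oracle 10⁻⁶ Å, dihedrals vs
four-point oracle 10⁻⁹ degrees.

## Known limitations

* Symmetry classification assumes at most two protofilaments; wider
  assemblies (outer density layers, 4-subunit packings) are out of scope.
* The C₁ repeat convention (two layers, two molecules) matches the
  two-inequivalent-subunit case; other C₁ arrangements would need an
  explicit `molecules_per_repeat`.
* The hydrogen-bond and contact cutoffs are geometric defaults, not fitted
  to any deposition; they are exposed as parameters everywhere.
* `infer_layers_and_subunits` computes all-pair superpositions (O(n²) in
  chains); it is meant for refinement-scale segments (≤ tens of chains),
  not the hundreds-of-layer stacks used for width profiling, which carry
  their generation ground truth instead.
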