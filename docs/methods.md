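# Methods

## Point groups and canonical orientations

The chiral cubic groups are built by closing generator sets under matrix
multiplication and verifying the expected orders (T: 12, O: 24, I: 60)
exactly. Orientation conventions are fixed once so that axis lists, dock
identifiers, and output files are reproducible:

* **T, O** — two-fold / four-fold axes along the coordinate axes, a
  three-fold along (1,1,1).
* **I** — the "222" setting: three mutually perpendicular two-fold axes
  along x, y, z; five-fold axes through icosahedron vertices at cyclic
  permutations of (0, ±1, ±φ), with φ the golden ratio.

Group elements are ordered deterministically (identity first, then by trace
descending with a lexicographic tie-break). Axes are classified by the
*maximal* cyclic order realized about their direction, giving the classical
census (T: 3×C2 + 4×C3; O: 6×C2 + 4×C3 + 3×C4; I: 15×C2 + 10×C3 + 6×C5),
and stored undirected; the docking flip degree of freedom covers both
orientations of a block on an axis, which avoids double-counting docks.
Group identities are checked to 1e-9; coordinate identities after symmetry
expansion to 1e-6 Å. Expansion applies one left-coset representative of the
Cn subgroup per building block, with the identity always first, so block 0
of an expanded assembly is the input block bitwise.

## Building blocks

A building block is a Cn homomer: equal-length chains with identical
sequence. The cyclic axis is detected by fitting a single optimal rigid
superposition (Kabsch, via scipy's `Rotation.align_vectors`) mapping the
chain concatenation (0, 1, …, n−1) onto its cyclic shift; the rotation axis
of that generator is the symmetry axis, and its RMSD is the reported
symmetry deviation. Fitting all cyclic mappings jointly is better
conditioned than averaging per-pair fits and exact for a true Cn oligomer.
Blocks with symmetry RMSD above 0.5 Å (configurable) are rejected as
asymmetric.

Canonicalization maps the axis to +z, the centroid to the origin, and fixes
the in-plane orientation by zeroing the azimuth of chain 0's centroid (its
first residue when the centroid is axial). The map is idempotent (already
canonical blocks are returned bitwise unchanged) and invariant under rigid
pre-motion. For dimers the axis direction is sign-ambiguous; both signs are
tried and the lexicographically smaller rounded coordinate array kept, a
deterministic, frame-independent tie-break. For n ≥ 3 the sign is fixed by
requiring a positive rotation to map chain i onto chain i+1.

### Synthetic generator

The generator emulates the *output contract* of generative backbone design —
an idealized Cn oligomer with exact internal symmetry — not its
conformational diversity. One protomer is built (an α-helical hairpin with
ideal helix parameters 2.30 Å radius, 1.51 Å rise, 99.6°/residue, laid out
radially; or a degenerate zigzag trace for fast tests), given mild
deterministic coordinate texture, placed with its centroid 11 Å from the z
axis by default, and replicated by exact Cn rotations. The 11 Å default was
chosen so that, for every supported cyclic order (2, 3, 4), the chains are
clash-free (minimum inter-chain Cα distance ≥ 3.5 Å) while still burying a
genuine chain–chain interface within 8 Å — both properties a designed
oligomer would have. Protomer lengths of 150 and 200 residues match the
design campaign scale; lengths 30–400 are accepted. Sequences are uniform
random draws over the 20-letter alphabet, so sequence-dependent statistics
(e.g. interface hydrophobicity) reflect the ~40% apolar background of the
alphabet, not designed interfaces — passing tests demonstrate the counting
and geometry machinery, not design quality.

### Motif stubs

The antigen-anchor emulation appends an idealized C3 coiled-coil stub
(superhelical radius 6.5 Å, default 7 residues — the C-terminal turn at the
base of a trimeric coiled coil) just beyond the block's top along its axis,
one strand per chain at 120° spacing. Pre-existing coordinates are preserved
bitwise. The stub sequence is a poly-alanine placeholder, and the recorded
motif span is exempted from the alanine-run filter, since motif residues are
sequence-variable during design. Placement verification measures the
perpendicular distance of the motif centroid from the block axis and the
motif's own cyclic-symmetry RMSD; when the block carries a stored axis
(canonical or by construction) that axis is used rather than re-detected,
because re-detection on a perturbed block would partially absorb the very
deviation being measured. Tolerances: 1.0 Å axis offset, 0.5 Å symmetry
RMSD.

## Docking

Placement composes, in order: optional flip (180° about x), rotation ω about
z, mapping of +z onto the target group axis, translation r along the axis,
then coset expansion. ω lives in the fundamental domain [0, 360/n).

Clash and contact counting consider only Cα pairs between chains of
*distinct* building blocks — the intra-oligomer interface is fixed upstream.
Clashes are strict (< cutoff: 3 Å for O4/I3, 2.5 Å for T2); contacts are the
closed band 3–8 Å. The contact threshold (≥ 10) is evaluated between the
reference block and its single highest-contact neighbor by default — the
designable two-fold nanoparticle interface — with an assembly-wide mode
available in configuration. Neighbor searches use a k-d tree with exact
distance re-checks, so counts equal a brute-force O(N²) enumeration exactly
(asserted against that oracle in the tests).

The dock score is the inter-block contact count itself, with clashing poses
at −∞. Residue-pair statistical potentials used by production docking
software require precomputed transform tables that are not portable;
published score thresholds tied to them (standard > 60 for T2/O4, > 70 for
I3; sasa > 5 for O4, > 6 for T2) are therefore documented here but not
implemented, and contact count — itself a published dock criterion — is the
ranking score. Grid defaults: ω step 2°, r step 1.0 Å coarse with 0.25 Å
refinement, r ∈ [0, 1.5 × block circumradius]. These were chosen so that a
fine-grid optimum is recoverable from a coarse scan plus 1-D translational
refinement at desk scale; tests and the acceptance script use coarser ω/r
grids (10–30°, 2–4 Å) on 40–60-residue fixtures to keep full scans in the
seconds-to-minutes range. Ranking is deterministic: score descending, then
(ω, r, flip) ascending.

## Design filter cascade

Stages are independent predicates applied in a configurable order (the
survivor set is order-invariant, asserted by test): alanine party (a maximal
run of ≥ 4 consecutive alanines outside the motif span), degreaser
(ddG_ins,pred < 2.6), pLDDT > 90, pAE < 5, ddG < −10, and an optional manual
exclusion list standing in for visual inspection. All inequalities are
strict as printed; "cutoff of −10" is read as ddG < −10, consistent with the
other thresholds. pLDDT, pAE, ddG and ddG_ins,pred are pass-through inputs
produced by external predictors; a record missing a metric is marked
*skipped* for that stage — tallied separately from failures in the attrition
table — and never survives, since an unevaluated design cannot be advanced.

## Structure comparison

RMSDs are Cα-based, computed after least-squares proper superposition.
Because assembly chains can be relabeled by any symmetry operation, the
chain correspondence is recovered by **anchored propagation**: superpose one
chain of the model onto each reference chain in turn, carry the implied
rigid transform to all model chain centroids, assign chains by nearest
centroid (Hungarian assignment), and keep the correspondence minimizing the
global RMSD. This is exact for near-symmetric structures at a cost linear in
the chain count, rather than factorial. The search runs in both directions
and reports the minimum, making the measure symmetric in its arguments to
1e-6 Å.

Three comparison levels mirror design-accuracy reporting: the full assembly;
the pair of building blocks sharing the highest-contact two-fold interface
(each assembly's pair identified independently from its own contact
census); and a single building block. At the building-block level the
reference oligomer is taken from the full-assembly chain map rather than by
choosing the best-RMSD block — minimizing over all 12/24/60 independently
perturbed blocks would bias the estimate low (order-statistics selection of
roughly −6% at trimer size).

Model and reference chains are matched residue-by-index after trimming both
to the shorter common length from the C terminus (unresolved termini);
diverging sequences are a hard error — no sequence alignment is attempted.

Interface residues are those whose Cα lies within 8 Å (the contact-band
upper bound) of any Cα in a partner chain: partners within one block for the
oligomeric class, across blocks for the nanoparticle class. A Cα criterion
is used because design-stage models may lack side chains; it is coarser than
buried-surface-area definitions, so absolute hydrophobic fractions are
definition-dependent and every report records the residue set and apolar
alphabet used (default {A,V,L,I,M,F,W,C}). An empty interface yields an
undefined (absent) fraction, never 0.

## Numerical and I/O conventions

Coordinates in Å, right-handed frame, residues 1-based and contiguous per
chain; ranges inclusive. mmCIF is the canonical output (legacy PDB for ≤ 62
chains, auth chain IDs A–Z, a–z, 0–9 in provenance order). Group/axis dumps
carry 17 significant digits. A single top-level seed drives every random
draw; generator outputs are bitwise deterministic for a fixed seed.

## Known limitations

* Backbone generation, sequence design, structure prediction, and energy
  evaluation are all external: this toolkit consumes their outputs (or
  synthetic stand-ins) and owns only the geometry, filtering, and analysis
  between them.
* The contact-count dock score ranks poses by interface size only; it does
  not capture shape complementarity or chemistry, so its rankings are not
  comparable to statistical-potential scores beyond the pass/fail filters.
* The synthetic generator produces idealized, exactly symmetric, clash-free
  blocks; it does not emulate backbone diversity, loop irregularity, or the
  near-symmetric noise of predicted structures (tests cover that regime
  separately by perturbing assemblies).
* Whether the published contact threshold was applied per interface or
  assembly-wide is not documented; both modes are provided, with
  best-neighbor as default.
* The anchored-propagation correspondence search is exact only for
  near-symmetric assemblies; grossly distorted structures may require an
  exhaustive search it does not attempt.
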