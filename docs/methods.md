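# Methods

This note records the modelling choices behind `ifacesearch`: what the
method assumes, which parameters matter, what the synthetic fixtures do and
do not emulate, and where the design was genuinely open.

## Interface model

Interface membership is atom-level: a heavy atom belongs to its chain's
side of the interface iff it lies within the contact cutoff (4.5 Å) of any
heavy atom of the partner chain. Residue-level definitions (the whole
residue joins if one atom is close) are common in other tools; the
atom-level reading matches the phrasing of the method this package
implements and produces tighter point clouds. Hydrogens are discarded at
parse time and no protonation states are predicted: all typing operates on
heavy atoms, which is why histidine is typed as an ambiguous
donor/acceptor and the backbone amide/carbonyl split is done purely by
atom name.

Alternate locations keep the highest-occupancy conformer, ties broken by
the alphabetically first altloc id. UNK residues are retained with
element-level typing so unknown-sequence models do not break the pipeline.
Coordinates are Å as authored; residue numbering, including insertion
codes, is preserved.

### Solvent exposure

The restricted/all point modes keep only atoms that are solvent-exposed on
the *unbound* chain (the partner removed first — interface atoms must not
be pre-buried by the very contact being modelled). Exposure is per-atom
Shrake–Rupley SASA: 960 golden-spiral test points, probe 1.4 Å,
Bondi-type heavy-atom radii, exposed iff area > 0.1 Å². The source method
states that exposure is used but not how it is computed; these are this
package's explicit substitutes, and the implementation is cross-checked in
the tests against Biopython's independent Shrake–Rupley (agreement within
the sphere-discretization quantum, ~0.1 Å² per test point). Aromatic ring
centres count as exposed irrespective of their ring atoms.

### Pharmacophore typing

The published scoring matrix defines the eight-type alphabet but not the
assignment rules; the decision table here follows standard pharmacophore
conventions: backbone O → Acc, backbone N → Don, OXT → Neg/Acc;
Ser OG/Thr OG1/Tyr OH/Cys SG/His ND1,NE2 → Acc/Don; Asn/Gln amide O → Acc
and amide N → Don; Trp NE1 → Don; Lys NZ and Arg NE/NH1/NH2 → Pos/Don;
Asp/Glu carboxylate O → Neg/Acc; Met SD → Acc; ring centres → Aro;
non-aromatic side-chain carbons → HyPhob; every Cα → its own type;
anything else (notably the backbone carbonyl carbon) → Other, which never
contributes pharmacophore credit. Lys CB–CD counting as hydrophobic
follows the method's explicit listing of Lys among hydrophobic side-chain
carbon contributors.

## Search

Tetrahedron enumeration is exhaustive over all 4-subsets whose six
pairwise distances lie in [minDist, maxDist], implemented as clique
enumeration on the in-range graph (identical output to the brute-force
subset scan, which the tests verify). Beyond 120 points the scan is
restricted to each point's 20 nearest in-range neighbours; the default Cα
representation keeps interfaces far below that bound, so the cap rarely
binds.

Filter selection is a greedy cover in decreasing-size order (a tetrahedron
is kept iff it covers a not-yet-covered point), topped up with the largest
remaining tetrahedra to `noffilters`; if the cover alone exceeds
`noffilters`, its largest members are kept. The published selection
sentence is ambiguous between capping the cover and capping all
candidates; covering the complete query interface is the stated goal, so
the cover is preferred. Ties throughout are broken by lexicographic corner
indices — an arbitrary but fixed rule needed for bit-identical reruns.

Matching joins candidate corners smallest-candidate-set first under the
toleranced distance predicates. All symmetric/overlapping mappings are
kept (each yields its own alignment); a safety cap of 10,000 mappings per
(filter, target) guards against pathological repeats in homopolymers. The
store is a single SQLite file plus a JSON manifest — the desk-scale
counterpart of the server database the original backend uses; whether
distance predicates run in SQL or in memory is behaviourally irrelevant
and here they run in memory.

## Alignment and scores

Superposition is the closed-form Kabsch–Umeyama solution with the
determinant correction, so reflections can never be returned. Matches
whose four corners are coplanar or collinear (smallest singular value of
the centred coordinates < 1e-6) are discarded: their superposition is
unstable and real 3-D patches offer non-degenerate alternatives.

The prefilter is a pure ranking stage — the Cα shape score at a fixed 6 Å
radius, no absolute threshold (none is published). Per target, the best
⌈√n⌉ of n candidates advance (ceiling chosen; rounding is unstated), ties
broken by lower corner RMSD. Final scores divide by the point count of
the larger compared side, so the SP-score lives in [0, 1] and equals 1
exactly for self-comparison; "equally weighted" is implemented as the
arithmetic mean, keeping the combined score on the same scale as its
parts. Nearest-neighbour search is a linear scan below 100 eligible
points and a k-d tree above; the two paths are exact-equal by
construction and by test. With `twoSidedScoring` the partner-side pairing
is scored under the same transform and the two results averaged — the
published description says only that both interfaces are considered, so
the mean is this package's reading.

## Synthetic complexes

The generator exists so every stage is testable without downloads. Chains
are compact bundles of near-ideal secondary-structure segments (two
antiparallel helices, or three strands as a sheet) built by
internal-coordinate chain growth with standard bond lengths/angles and
motif torsions carrying σ = 6° per-residue heterogeneity. The
heterogeneity matters: perfectly ideal segments make independently
generated complexes share one exact coordinate lattice, and unrelated
interfaces then align perfectly — a geometric artefact no real pair of
proteins exhibits. Straight single segments were rejected for the
complementary reason: rigid ideal chains touch along a one-dimensional
stripe longer than `maxDist`, which starves the tetrahedron generator.

Chains are packed face-to-face at a controllable closest heavy-atom
contact distance (default 3.8 Å, the van der Waals contact real
interfaces show, comfortably inside the 4.5 Å membership cutoff), with the
flattest surface stripe oriented toward the partner and an induced-fit
step that draws side chains within 8.5 Å into the contact band — the
surface complementarity of real interfaces, imposed geometrically.
Interfaces come out at 7–20 points per side in Cα mode.

Similar decoys are the base complex under a random rigid motion, Gaussian
coordinate noise (default σ = 0.3 Å), and alanine truncation of a
fraction (default 0.2) of non-interface residues. Dissimilar decoys are
fresh complexes with varied length (24–40 residues), motif, packing angle
(±60°) and contact distance (3.8–4.5 Å). What passing tests show is that
the geometry/typing/matching machinery is correct and discriminative on
clouds with realistic size and contact statistics; they do not show
performance on real structures, where flexibility, crystal contacts,
non-standard residues and genuinely homologous decoys make the screening
problem harder.

## Problem sizes and numerics

The test suite and benchmark use deliberately small instances: 25 fixture
complexes for the self-similarity and motion-recovery suites, a
200-interface panel (10 planted similars, 190 unrelated) for the
enrichment check, oracle comparisons on targets of ≤ 15 points (where
exhaustive ordered-4-tuple enumeration is feasible), and 10,000-rotation
Monte-Carlo baselines for the superposition. These sizes make every
expected value computable by an independent brute-force path while
exercising the same code that would run on real structures.

Numerical conventions: orthogonality/determinant tolerances of 1e-8 on
rotations; the degeneracy threshold 1e-6 on singular values; EF top-list
size ⌈f·N⌉ (ceiling); normalized EF = retrieved actives / min(A, ⌈f·N⌉);
AUC by the rank-sum formulation with ties counting ½. Score ties during
ranking keep stable input order, so reruns are byte-identical.

## Known limitations

- One structural model per file is used (the first); no assemblies,
  symmetry expansion, or nucleic-acid chains.
- Pharmacophore typing is heuristic on heavy atoms; no protonation,
  tautomer, or explicit interaction-type inference.
- Nearly collinear interfaces (e.g. a single β-strand edge-on) admit few
  or no valid tetrahedra — inherent to tetrahedral hashing with a
  14 Å edge bound, and mirrored by the strand-motif generator producing
  exactly this hard case.
- The match cap (10,000 per filter and target) can truncate mappings in
  highly repetitive interfaces; a warning is logged when it binds.
- Scores carry no statistical significance estimate; they are similarity
  measures, not p-values.
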