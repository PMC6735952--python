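# Methods

`g4kit` annotates the architecture of G-quadruplex (G4) DNA from atomic
coordinates: which guanines form Hoogsteen-bonded tetrads, how the tetrads
stack, whether each guanine–guanine (GG) step progresses with a right- or
left-handed screw sense, where a right/left junction sits and what its
interface looks like, plus the standard NMR-restraint bookkeeping and
ensemble RMSD statistics that accompany such a structure determination.
This note records the models, conventions and numerical choices behind each
stage, and what the synthetic test structures do and do not establish.

## Tetrad detection

A G-tetrad is a planar cycle of four guanines in which each base donates
its N1/N2 (Watson–Crick) face to the O6/N7 (Hoogsteen) face of the next.
Detection is a three-stage procedure:

1. **Standard base frames.** A rigid idealized guanine (the nine purine
   ring atoms plus O6, N2 and C1′; ideal coordinates from the wwPDB
   chemical component dictionary) is least-squares fitted to each observed
   guanine base. All hydrogen-bond geometry is then measured between
   *fitted* atom positions. Fitting averages the coordinate noise of the
   twelve fitted atoms, so the positional uncertainty of any single atom
   (typical of both experimental coordinates and jittered synthetic
   models) barely perturbs the measured N···N/N···O distances; with
   independent per-atom Gaussian noise of 0.2 Å per component, the fitted
   H-bond distance noise is ≈0.11 Å versus ≈0.28 Å for raw atoms. C1′ is
   part of the frame because its position relative to the base is
   invariant to the glycosidic torsion. Raw proton distances (H21–N7,
   H1–O6) are reported alongside when hydrogens are present.
2. **Directed Hoogsteen pairs.** Donor→acceptor guanine pairs are reported
   when both fitted heavy-atom distances N2–N7 and N1–O6 fall inside
   [2.4, 3.4] Å. The window is centred on the 2.9 Å restraint targets used
   in G4 NMR refinement and widened by ±0.5 Å to tolerate real-structure
   variation; the identification window is a package choice, since
   refinement protocols impose rather than detect these bonds.
3. **Cycle assembly.** Tetrads are the simple directed 4-cycles of the
   pair graph. A candidate cycle is rejected when any member's base normal
   tilts more than 25° from the cycle's mean plane normal (this planarity
   filter suppresses accidental cycles through stacked layers). If two
   accepted cycles share a guanine, the one with the lower mean heavy-atom
   H-bond distance wins and the rest are re-evaluated — a deterministic
   greedy rule. Member order is canonicalized to start at the lowest
   (chain, residue) key, running in donor→acceptor direction.

The stack axis is the principal direction of the tetrad centroids (the
plane normal for a single tetrad), oriented 5′→3′ along the strand that
contains the lowest-numbered core guanine. Layers are indexed from the
5′-most tetrad; consecutive centroid separations must lie in [2.5, 4.5] Å
or the stack is reported as ambiguous. The two terminal layers are
`outer`, the rest `inner`; imino protons of inner-layer guanines are
predicted solvent-exchange `protected`, outer-layer ones `exchanging`.

## Cyclic polarity

The polarity of a tetrad is the sense of its donor→acceptor cycle for a
viewer looking along a chosen axis (by default the 5′→3′ stack axis, i.e.
the view from the 5′ side). The member base-ring centroids are projected
onto the plane perpendicular to the axis and the signed area of the
traversal is computed; a negative signed area about the view axis is
reported `clockwise`. The sign convention is anchored to guanine geometry:
building an idealized parallel tetrad from real guanine coordinates and
viewing it from the 5′ side of a right-handed parallel block yields a
clockwise cycle, the orientation reported for right-handed parallel G4s.
Polarity flips under coordinate mirroring and under view-axis reversal,
and is invariant under rigid motion.

## GG-step handedness and blocks

For each pair of sequence-adjacent core guanines in adjacent layers, the
classifier compares two vectors: the C5′→C3′ vector of the 5′ residue's
sugar, and the progression vector from the 5′ residue's tetrad centroid to
the 3′ residue's tetrad centroid. An angle below 90° − ε means a
right-handed step, above 90° + ε left-handed, and within ±ε (default 1°)
ambiguous — the band prevents numerical noise from flipping calls near the
boundary. The 5′ sugar is used because it sits at the layer the
progression vector leaves; a flag computes the 3′ alternative for
comparison.

The two vectors are mirrored together by a reflection, so their angle
alone cannot sense chirality — the <90°/>90° rule presumes D-deoxyribose.
The classifier therefore also determines the enantiomer of the 5′ sugar by
superposing the idealized D-sugar fragment (C1′–C5′, O4′, O3′, N9) and its
mirror image onto the observed atoms (proper rotations only) and keeping
the better fit; for an L-sugar the call is swapped. On physical D-DNA this
changes nothing; on mirrored coordinates the reported handedness is the
handedness the mirrored structure actually has. Enantiomer-by-best-fit is
far more noise-tolerant than a signed-volume test at a single stereocentre
because it pools all sugar atoms.

Blocks are maximal runs of layers whose connecting steps agree; the call
joining two layers is the majority over its (≤4) steps, with ties,
ambiguous calls, or absent steps acting as block boundaries. Strand
polarity (parallel / antiparallel / hybrid) comes from the sign pattern of
per-strand 5′→3′ directions against the stack axis.

## Junctions

For each adjacent block pair the junction record contains: the polarity
relation of the two interface tetrads (`same`/`opposite`, both viewed
along the common stack axis); the inter-block sugar contacts, paired
greedily by nearest C1′–C1′ distance under a 5.5 Å cutoff (H1′–H1′
distances reported when protons exist); and a 5/6-ring stacking mode per
contact pair, assigned by projecting the upper guanine's five- and
six-ring centroids onto the lower partner's base plane and taking the
laterally nearest ring within 2.5 Å (`none` beyond). The mode string is
ordered upper/lower. The lateral cutoff is a documented package choice;
the mode is validated qualitatively on generator output only.

## Torsions

Backbone angles α–ζ follow the standard nucleic-acid atom quartets; the
purine glycosidic angle χ is O4′–C1′–N9–C4. Backbone angles are reported
on (−180, 180], χ on [0, 360) — the convention in which the anti window is
written 240 ± 70°. χ ∈ [170, 310] (closed) classifies `anti`; [0, 120)
classifies `syn`; anything else is `undefined`. The syn band only guards
against misbuilt inputs — the structures this package targets are
all-anti. Angles with missing defining atoms are absent, never zero.
Per-block summaries use circular (vector-resultant) means and standard
deviations, since plain averages are wrong near the ±180° wrap; an
exclusion list removes divergent steps from summaries.

## Restraint engine

A declarative topology (tetrads in cyclic order, outer/inner positions,
syn/anti assignments, NOE peak list; YAML on disk) expands to:

| restraint | rule | values |
|---|---|---|
| Hoogsteen H-bonds | 4 per directed pair, 16 per tetrad | H21–N7 2.0±0.2, N2–N7 2.9±0.3, H1–O6 2.0±0.2, N1–O6 2.9±0.3 Å |
| χ dihedral | 1 per anti core guanine | 240° ± 70 (outer) / ± 40 (inner) |
| planarity | 1 group per tetrad | weight 1 kcal mol⁻¹ Å⁻² (annotation) |
| NOE | from class table | non-exch 2.7±0.8 / 3.8±0.9 / 4.6±1.2 / 5.5±1.7 Å; exch 4.0±1.2 / 4.8±1.4 / 5.5±1.7 Å; methyl 4.0±1.2 / 4.8±1.4 / 5.5±2.2 Å |

Distance restraints are flat-bottom wells [target−minus, target+plus]; a
model violates one when the measured distance leaves the well by more than
the violation threshold (0.2 Å default), matching the ">0.2 Å" accounting
convention of NMR structure statistics. Dihedrals are violated when the
circular distance from the centre exceeds the width. Restraints on missing
atoms (e.g. protons in crystal structures) are counted unevaluable, never
violated. Planarity is reported as the RMS out-of-plane deviation of the
group's base atoms against a 0.5 Å threshold — a package convention, since
refinement protocols define planarity as an energy term, not a violation.
Export dialects: XPLOR/CNS-style `.tbl` (`assign` records) and TSV. The
amino-proton naming follows the G4 NMR literature (H21 = the proton syn to
N1, donated to N7).

## Superposition

Rigid-body fits use the SVD (Kabsch) algorithm with reflections excluded,
so chirality is never silently inverted. Ensemble statistics follow the
NMR convention: all unordered model pairs are superposed on a named
selection (optionally minus an exclusion list) and mean ± sample sd of the
pairwise RMSDs is reported. Selections are canonical-ordered and
heavy-atom only; the G-tetrad-core selection takes the core guanines'
heavy atoms, with a base-only variant available since published values do
not always state the selection used.

## The synthetic generator

The generator emulates the geometry of parallel-stranded G4 cores with
controlled handedness. A tetrad layer is built from a rigid idealized
guanine nucleotide: under C4 symmetry the two heavy-atom Hoogsteen
distances determine the tetrad up to global rotation, and the in-plane
pose is solved in closed form (two circle equations), selecting the branch
with near-linear N–H···X geometry. The natural 5-ring-centroid radius at
2.9 Å targets is ≈5.64 Å (the default); other radii in [4, 6] Å are
reached by letting the base tilt slightly while keeping heavy-atom
contacts within 2.9 ± 0.2 Å. The resulting layer puts O6 ≈2.2 Å from the
axis — the K⁺-channel geometry of real G4s — and its proton distances
(H21–N7, H1–O6 ≈ 1.95 Å) satisfy the restraint wells by construction.

Blocks stack layers with a signed per-layer twist (positive = right-handed
screw; defaults ±30°/layer) and a rise of 3.3 Å, four strands on chains
A–D numbered along layers so sequence adjacency equals layer adjacency.
χ is set to 240° (anti) on every guanine by rotating the sugar about the
glycosidic bond. The left-handed nucleotide orientation is produced by a
proper 180° rotation of the assembled tetrad about an in-plane axis —
never a mirror, which would invert sugar chirality. That flip reverses the
donor→acceptor sense *and* the axial component of the C5′→C3′ vector
simultaneously, reproducing the physical coupling between tetrad polarity
and helical handedness: right-handed blocks carry clockwise tetrads
(viewed from 5′) and sugar vectors below 90° to the progression, and
left-handed blocks the opposite. Because both hybrid blocks run 5′→3′
along the same axis, the two interface tetrads carry opposite polarity by
construction, as at a real right/left junction.

The hybrid places the left-handed block below the right-handed one,
separated by 3.4 Å, and chooses the upper block's azimuth by a
deterministic 2° scan minimizing the worst of the four interface C1′–C1′
contacts (all ≤5.5 Å). Jitter is iid per-atom Gaussian displacement with a
seed. Ground truth (tetrad membership per layer, per-step handedness,
block boundaries, junction pairs and polarity relation, per-residue χ) is
emitted with every model.

**What generator-based tests show — and don't.** Passing the
analyzer–generator closure grid (twist ±15°/±30°, 2–4 layers, jitter up to
0.2 Å) shows the full chain of definitions is self-consistent, correctly
oriented (right ⇒ clockwise ⇒ <90°), and robust to uncorrelated
coordinate noise at the scale of typical coordinate uncertainty. It does
not exercise syn guanines, bulges, mixed tetrads, loops (an option adds
thymine stubs purely so exclusion-mask code paths run), antiparallel
topologies, ions, or the correlated deformations of real ensembles.
Checks against deposited hybrid-quadruplex coordinates are provided as a
separate integration script (`scripts/analyze_deposited.py`) that runs on
locally downloaded files.

## Numerical choices and degenerate inputs

* Hoogsteen window [2.4, 3.4] Å on fitted distances; planarity filter 25°;
  ambiguity band ε = 1° at 90°; junction cutoffs 5.5 Å (C1′–C1′) and
  4.0 Å (H1′–H1′, reporting only); stacking-mode lateral cutoff 2.5 Å.
* Altlocs: the highest-occupancy conformer per atom is used for analysis,
  ties broken by altloc character; waters/ions are parsed but excluded
  from geometry; unknown residue names are retained but never selected.
* Collinear torsion quartets, zero-length vectors and degenerate
  projections raise explicit geometry errors rather than returning
  arbitrary values; empty restraint sets refuse to export; stacks whose
  layer separations leave [2.5, 4.5] Å raise an ambiguity error naming the
  offending layers.
* Circular means use the vector resultant; the resultant length is clamped
  to 1 before the dispersion logarithm.

## Known limitations

* Tetrad detection assumes guanine-only tetrads (no mixed or bulged
  tetrads) and does not analyze ion coordination.
* The handedness rule needs sugar atoms; steps missing C5′/C3′ are
  reported ambiguous rather than guessed.
* Cross-construct superposition matches residues by sequence alignment
  plus exclusion lists; there is no structure-aware flexible alignment.
* The restraint engine books and checks restraints; it performs no
  simulated annealing, molecular dynamics or force-field scoring.
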