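# g4kit

Structural annotation of G-quadruplex (G4) DNA from atomic coordinates,
built around the geometry of hybrid right-/left-handed quadruplexes: a
single DNA chain can stack a right-handed parallel G4 block directly on a
left-handed one, and telling the two apart — per dinucleotide step, per
tetrad, and at the junction between them — is a well-defined geometric
problem that this package solves as a tested, reusable pipeline.

`g4kit` is for structural biologists and nucleic-acid modellers who have
coordinates (PDB/mmCIF — NMR ensembles, crystal structures, or models) and
want, without manual inspection:

* **G-tetrad detection** — directed Hoogsteen G•G pairs (donor N1/N2 face →
  acceptor O6/N7 face) found from a heavy-atom distance window measured on
  rigid standard-base-frame fits, assembled into planar 4-cycles, stacked,
  and labelled outer/inner with predicted imino-proton solvent-exchange
  protection.
* **Helical handedness per GG step** — the angle between the 5′ sugar's
  C5′→C3′ vector **s** and the tetrad-to-tetrad progression vector **p**:
  ∠(s, p) < 90° ⇒ right-handed, > 90° ⇒ left-handed (for D-sugar DNA; the
  sugar enantiomer is verified so mirrored coordinates are reported with
  their true handedness). Steps are segmented into handedness-uniform
  blocks.
* **Junction characterization** — relative cyclic polarity of the two
  interface tetrads (clockwise vs anticlockwise donor→acceptor cycle viewed
  from 5′), the four 5′-5′ sugar–sugar C1′/H1′ contacts, and 5/6-ring
  stacking modes.
* **Backbone torsions** (α–ζ, χ with syn/anti classification) and circular
  per-block summaries.
* **NMR restraint bookkeeping** — Hoogsteen hydrogen-bond, χ-dihedral,
  planarity and NOE-class distance restraints generated from a declarative
  topology, exported as XPLOR/CNS `.tbl` or TSV, and validated against any
  model with flat-bottom wells and a 0.2 Å violation threshold.
* **Superposition** — Kabsch RMSD (reflections excluded) with selections
  and exclusion lists, and ensemble pairwise-RMSD statistics.
* **A synthetic G4 generator** — idealized right-, left-handed and hybrid
  parallel cores with exact ground truth (tetrads, step calls, blocks,
  junction contacts, χ), so the whole pipeline is testable offline.

See `docs/methods.md` for the underlying conventions and numerical choices.

## Worked example

Generate an idealized hybrid (a two-layer left-handed block below a
two-layer right-handed block, joined 5′-5′), then analyze it:

```bash
g4kit simulate --layers 2,2 --handedness left,right \
               --out demo.pdb --truth demo_truth.json
g4kit analyze demo.pdb
```

Abridged output:

```json
{
 "blocks": [
  {"handedness": "left",  "layers": "0-1", "n_steps": 4, "strand_polarity": "parallel"},
  {"handedness": "right", "layers": "2-3", "n_steps": 4, "strand_polarity": "parallel"}
 ],
 "junctions": [
  {"interface": "G2•G2•G2•G2 | G101•G101•G101•G101",
   "polarity_relation": "opposite",
   "pair": "E/G101-A/G2", "d_C1_C1": 2.563, "d_H1_H1": 4.254, "stacking": "6/5"}
 ],
 "tetrads": [
  {"layer": 0, "tetrad": "G1•G1•G1•G1",         "polarity": "anticlockwise", "position": "outer"},
  {"layer": 1, "tetrad": "G2•G2•G2•G2",         "polarity": "anticlockwise", "position": "inner"},
  {"layer": 2, "tetrad": "G101•G101•G101•G101", "polarity": "clockwise",     "position": "inner"},
  {"layer": 3, "tetrad": "G102•G102•G102•G102", "polarity": "clockwise",     "position": "outer"}
 ]
}
```

Reading it: the analyzer recovered both blocks with their handedness and
parallel strand polarity; the left-handed block's tetrads cycle
anticlockwise and the right-handed block's clockwise (viewed from the 5′
side), so the junction stacks two tetrads of **opposite** polarity — the
signature of a right/left G4 junction — held by four inter-block
sugar–sugar contacts (C1′–C1′ 2.6 Å, H1′–H1′ 4.3 Å here). The report also
contains per-step angles, torsion tables and the exchange-protection
partition (inner-layer guanines protected, outer exchanging).

Restraints for the hybrid-quadruplex topology shipped with the package
(four tetrads, 16 anti core guanines):

```bash
g4kit restraints src/g4kit/data/tba_tt_block2.yaml --dialect tsv --out restraints.tsv
# stderr: {"counts": {"hbond": 64, "noe": 0, "dihedral": 16, "planarity": 4}}
```

64 hydrogen-bond restraints (16 per tetrad: H21–N7 2.0±0.2 Å, N2–N7
2.9±0.3 Å, H1–O6 2.0±0.2 Å, N1–O6 2.9±0.3 Å), 16 χ restraints (240°, ±70°
outer / ±40° inner) and 4 planarity groups.

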