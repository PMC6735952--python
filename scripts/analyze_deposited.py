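#!/usr/bin/env python
"""Validate the analysis stack against the deposited coordinates.

This integration harness needs locally downloaded coordinate files (they
are not shipped with the package and the test suite never requires them):

* the NMR ensemble of the hybrid right-/left-handed quadruplex
  (PDB entry 6JCE, 10 models, 28-nt construct), and
* optionally the crystal structure of the single-T-linker construct
  (PDB entry 6QJO, 4 molecules per asymmetric unit).

Checks performed on the NMR entry: the four detected tetrads are
G2•G6•G11•G15, G1•G5•G10•G14, G18•G21•G24•G27 and G20•G23•G26•G29; the TBA
block classifies right-handed and the Block2 block left-handed; the four
inter-block sugar contacts pair G1/G27, G5/G24, G10/G21 and G14/G18; the
predicted rapidly exchanging guanines are G2, G6, G11, G15, G20, G23, G26,
G29; and the ensemble pairwise heavy-atom RMSD is reported for the
G-tetrad-core and all-heavy selections (published: 0.822 and 2.359 Å).
With the crystal file, the four molecules' pairwise guanine-core RMSD is
reported (published: 0.347 Å) and the NMR/crystal cross RMSD excluding
T4, T7, T13 and T17 (published: 1.62 Å).

Usage:
    python scripts/analyze_deposited.py --nmr 6jce.pdb [--crystal 6qjo.cif]
"""

from __future__ import annotations

import argparse
import difflib
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

from g4kit import handedness as hd        # noqa: E402
from g4kit import tetrad_core as tc      # noqa: E402
from g4kit.structure_io import Ensemble, read_structure, select_atoms  # noqa: E402
from g4kit.superpose import ensemble_pairwise_rmsd, superpose  # noqa: E402

EXPECTED_TETRADS = [
    {2, 6, 11, 15}, {1, 5, 10, 14}, {18, 21, 24, 27}, {20, 23, 26, 29}]
EXPECTED_CONTACTS = {frozenset(p) for p in
                     [(1, 27), (5, 24), (10, 21), (14, 18)]}
EXPECTED_EXCHANGING = {2, 6, 11, 15, 20, 23, 26, 29}
TBA_GUANINES = {1, 2, 5, 6, 10, 11, 14, 15}


def check(name: str, ok: bool, detail: str = "") -> bool:
    print(f"[{'PASS' if ok else 'FAIL'}] {name}" + (f" — {detail}" if detail else ""))
    return ok


def core_guanine_keys(model):
    tetrads = tc.assemble_tetrads(tc.detect_hoogsteen_pairs(model))
    return sorted({k for t in tetrads for k in t.member_keys}), tetrads


def sequence_mapping(model_a, model_b):
    """Residue-key mapping between constructs by one-letter alignment."""
    ra = [r for r in model_a.polymer_residues()]
    rb = [r for r in model_b.polymer_residues()]
    sa = "".join(r.base or "X" for r in ra)
    sb = "".join(r.base or "X" for r in rb)
    sm = difflib.SequenceMatcher(a=sa, b=sb, autojunk=False)
    mapping = {}
    for i, j, size in sm.get_matching_blocks():
        for k in range(size):
            mapping[ra[i + k].key] = rb[j + k].key
    return mapping


def analyze_nmr(path: str) -> bool:
    ens = read_structure(path)
    model = ens.models[0]
    ok = True

    keys, tetrads = core_guanine_keys(model)
    got_sets = sorted(sorted(r[1] for r in t.member_keys) for t in tetrads)
    want = sorted(sorted(s) for s in EXPECTED_TETRADS)
    ok &= check("four published tetrads detected", got_sets == want,
                f"{got_sets}")

    stack = tc.order_stack(tetrads, model)
    steps = hd.enumerate_gg_steps(model, stack)
    blocks = hd.segment_blocks(steps, stack, model)
    hand_by_block = {}
    for b in blocks:
        nums = {r[1] for t in stack.tetrads if t.layer_index in b.layers
                for r in t.member_keys}
        label = "TBA" if nums & TBA_GUANINES else "Block2"
        hand_by_block[label] = b.handedness
    ok &= check("TBA block right-handed",
                hand_by_block.get("TBA") == "right", str(hand_by_block))
    ok &= check("Block2 block left-handed",
                hand_by_block.get("Block2") == "left", str(hand_by_block))

    junctions = hd.detect_junction(blocks, stack, model)
    pairs = {frozenset((ru.seq_number, rl.seq_number))
             for j in junctions for ru, rl, _, _ in j.sugar_contacts}
    ok &= check("four 5'-5' sugar contacts", pairs == EXPECTED_CONTACTS,
                str(sorted(map(sorted, pairs))))

    part = tc.predict_exchange_protection(stack)
    exch = {r.seq_number for r in part["exchanging"]}
    ok &= check("rapidly exchanging guanines", exch == EXPECTED_EXCHANGING,
                str(sorted(exch)))

    core_labels = [f"G{n}" for s in EXPECTED_TETRADS for n in sorted(s)]
    mean_core, sd_core, _ = ensemble_pairwise_rmsd(
        ens, selection="by-residue-list", residues=core_labels)
    ok &= check("ensemble core RMSD ≈ 0.822 Å",
                abs(mean_core - 0.822) <= 0.15, f"{mean_core:.3f} ± {sd_core:.3f}")
    mean_all, sd_all, _ = ensemble_pairwise_rmsd(ens, selection="heavy")
    ok &= check("ensemble all-heavy RMSD ≈ 2.359 Å",
                abs(mean_all - 2.359) <= 0.35, f"{mean_all:.3f} ± {sd_all:.3f}")
    return ok


def analyze_crystal(path: str, nmr_path: str | None) -> bool:
    ens = read_structure(path)
    model = ens.models[0]
    ok = True
    chains = sorted({r.chain_id for r in model.polymer_residues()})
    mols = []
    from g4kit.structure_io import StructureModel
    for ch in chains:
        mols.append(StructureModel(1, [r for r in model.residues
                                       if r.chain_id == ch]))
    vals = []
    for i in range(len(mols)):
        for j in range(i + 1, len(mols)):
            gi = [(r, a) for r, a in select_atoms(mols[i], "heavy")
                  if r.base == "G"]
            gj = [(r, a) for r, a in select_atoms(mols[j], "heavy")
                  if r.base == "G"]
            keyed_i = {(r.seq_number, a.name): a.coords for r, a in gi}
            keyed_j = {(r.seq_number, a.name): a.coords for r, a in gj}
            common = sorted(set(keyed_i) & set(keyed_j))
            if len(common) < 3:
                continue
            A = np.array([keyed_i[k] for k in common])
            B = np.array([keyed_j[k] for k in common])
            vals.append(superpose(A, B).rmsd)
    if vals:
        mean = float(np.mean(vals))
        ok &= check("crystal guanine-core pairwise RMSD ≈ 0.347 Å",
                    abs(mean - 0.347) <= 0.15, f"{mean:.3f} over {len(vals)} pairs")
    if nmr_path:
        nmr = read_structure(nmr_path).models[0]
        mapping = sequence_mapping(nmr, mols[0])
        skip_nmr = {k for k in mapping
                    if nmr.residue(k).label in ("T4", "T7", "T13", "T17")}
        common = [(ka, kb) for ka, kb in mapping.items() if ka not in skip_nmr]
        pa, pb = [], []
        for ka, kb in common:
            res_a, res_b = nmr.residue(ka), mols[0].residue(kb)
            names = ({a.name for a in res_a.atoms if a.element != "H"}
                     & {a.name for a in res_b.atoms if a.element != "H"})
            for n in sorted(names):
                pa.append(res_a.coord(n))
                pb.append(res_b.coord(n))
        rmsd = superpose(np.array(pa), np.array(pb)).rmsd
        ok &= check("NMR/crystal cross RMSD ≈ 1.62 Å",
                    abs(rmsd - 1.62) <= 0.25, f"{rmsd:.3f} ({len(pa)} atoms)")
    return ok


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--nmr", required=True, help="NMR ensemble file (6JCE)")
    ap.add_argument("--crystal", default=None, help="crystal file (6QJO)")
    args = ap.parse_args()
    ok = analyze_nmr(args.nmr)
    if args.crystal:
        ok &= analyze_crystal(args.crystal, args.nmr)
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
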