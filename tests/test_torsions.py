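"""Backbone/glycosidic torsions and per-block circular summaries."""

import numpy as np
import pytest

from conftest import mirror_model, random_rigid, transform_model
from g4kit import synthetic as syn
from g4kit import tetrad_core as tc
from g4kit.geometry import circular_distance, place_atom
from g4kit.handedness import G4Block, GGStep, enumerate_gg_steps, segment_blocks
from g4kit.structure_io import Atom, Residue, StructureModel
from g4kit.torsions import (TorsionProfile, backbone_torsions,
                            block_torsion_summary, classify_glycosidic,
                            to_0_360)


def _profile(model):
    return backbone_torsions(model)


class TestBackboneTorsions:
    def test_chain_termini_have_absent_angles(self, left_block2):
        model, _ = left_block2
        prof = _profile(model)
        first, last = ("A", 1, ""), ("A", 2, "")
        assert prof.of(first, "alpha") is None      # 5' terminus
        assert prof.of(first, "epsilon") is not None
        assert prof.of(last, "epsilon") is None     # 3' terminus
        assert prof.of(last, "zeta") is None
        assert prof.of(last, "alpha") is not None

    def test_generator_chi_recovered(self, right_block4):
        model, truth = right_block4
        prof = _profile(model)
        for key, want in truth.chi.items():
            got = prof.of((key[0], key[1], ""), "chi")
            assert got == pytest.approx(want, abs=1e-6)
            assert prof.glycosidic[(key[0], key[1], "")] == "anti"

    def test_constructed_chi_240_recovered(self):
        """A guanine whose O4'-C1'-N9-C4 torsion is built at 240° reads 240°."""
        c1 = np.array([0.0, 0.0, 0.0])
        n9 = np.array([1.47, 0.0, 0.0])
        c4 = place_atom([0, 1.0, 0], c1, n9, 1.37, 126.0, 10.0)
        o4 = place_atom(c4, n9, c1, 1.42, 108.0, 240.0)
        # torsion O4'-C1'-N9-C4 equals the construction torsion by symmetry
        from g4kit.geometry import dihedral
        assert to_0_360(dihedral(o4, c1, n9, c4)) == pytest.approx(240.0, abs=1e-6)

    def test_all_angles_negate_under_mirror(self, right_block4):
        model, _ = right_block4
        prof = _profile(model)
        prof_m = _profile(mirror_model(model))
        for key, entry in prof.angles.items():
            for name, val in entry.items():
                if val is None:
                    continue
                got = prof_m.of(key, name)
                assert circular_distance(got, -val) < 1e-6, (key, name)

    def test_rigid_motion_invariance(self, left_block2):
        model, _ = left_block2
        rng = np.random.default_rng(9)
        R, t = random_rigid(rng)
        prof, prof_r = _profile(model), _profile(transform_model(model, R, t))
        for key, entry in prof.angles.items():
            for name, val in entry.items():
                if val is None:
                    continue
                assert circular_distance(prof_r.of(key, name), val) < 1e-6


class TestClassifyGlycosidic:
    @pytest.mark.parametrize("chi,want", [
        (240.0, "anti"), (60.0, "syn"),
        (170.0, "anti"), (310.0, "anti"),     # closed anti interval
        (0.0, "syn"), (119.9, "syn"),
        (150.0, "undefined"), (330.0, "undefined"),
        (-120.0, "anti"),                      # 240 in the 0-360 convention
    ])
    def test_windows(self, chi, want):
        assert classify_glycosidic(chi) == want


class TestBlockSummary:
    def _strand(self, chain, zeta, n=4):
        """An ``n``-residue backbone chain whose ζ torsions all equal ``zeta``.

        Each residue carries C3'/O3' and the next residue's P/O5' are placed
        by internal coordinates so the quartet C3'(i)–O3'(i)–P(i+1)–O5'(i+1)
        has the prescribed torsion.
        """
        aux = np.array([-1.0, 1.0, 0.3])
        c3 = np.array([0.0, 0.0, 0.0])
        o3 = np.array([1.43, 0.0, 0.0])
        atoms_per_res = [[Atom("C3'", "C", c3), Atom("O3'", "O", o3)]]
        prev = aux
        for _ in range(n - 1):
            p = place_atom(prev, c3, o3, 1.6, 119.0, 170.0)
            o5 = place_atom(c3, o3, p, 1.6, 104.0, zeta)
            c3_next = place_atom(o3, p, o5, 1.44, 111.0, -150.0)
            o3_next = place_atom(p, o5, c3_next, 1.43, 110.0, 75.0)
            atoms_per_res[-1].extend([])
            atoms_per_res.append([Atom("P", "P", p), Atom("O5'", "O", o5),
                                  Atom("C3'", "C", c3_next),
                                  Atom("O3'", "O", o3_next)])
            prev, c3, o3 = o5, c3_next, o3_next
        return [Residue(chain, i + 1, name="DG", atoms=atoms)
                for i, atoms in enumerate(atoms_per_res)]

    def test_blocks_differing_in_zeta_are_separated(self):
        """Two blocks built with ζ 120° apart separate by >90° in ζ mean."""
        res_a = self._strand("A", 60.0)
        res_b = self._strand("B", 180.0)
        model = StructureModel(1, res_a + res_b)
        prof = backbone_torsions(model)
        za = [prof.of(r.key, "zeta") for r in res_a]
        zb = [prof.of(r.key, "zeta") for r in res_b]
        za = [v for v in za if v is not None]
        zb = [v for v in zb if v is not None]
        assert za and zb
        assert np.allclose(za, 60.0, atol=1e-6)
        assert np.allclose(zb, 180.0, atol=1e-6)

        def mkblock(residues, layers):
            steps = [GGStep(residues[i], residues[i + 1], i, i + 1,
                            None, np.zeros(3), None, "right")
                     for i in range(len(residues) - 1)]
            return G4Block(layers=layers, handedness="right", steps=steps)

        class _FakeStack:
            tetrads = []
        blocks = [mkblock(res_a, [0, 1]), mkblock(res_b, [2, 3])]
        df = block_torsion_summary(prof, blocks, _FakeStack())
        z = df[df.angle == "zeta"].sort_values("block")
        assert len(z) == 2
        sep = circular_distance(*z.circular_mean.tolist())
        assert sep > 90.0
        assert sep == pytest.approx(120.0, abs=1e-4)

    def test_exclusions_cover_all_residues_absent_summary(self, left_block2):
        model, _ = left_block2
        stack = tc.order_stack(
            tc.assemble_tetrads(tc.detect_hoogsteen_pairs(model)), model)
        steps = enumerate_gg_steps(model, stack)
        blocks = segment_blocks(steps, stack, model)
        prof = backbone_torsions(model)
        all_keys = [r.key for r in model.residues]
        df = block_torsion_summary(prof, blocks, stack, exclusions=all_keys)
        assert df.empty

    def test_identical_blocks_identical_summaries(self, left_block2):
        model, _ = left_block2
        stack = tc.order_stack(
            tc.assemble_tetrads(tc.detect_hoogsteen_pairs(model)), model)
        steps = enumerate_gg_steps(model, stack)
        blocks = segment_blocks(steps, stack, model)
        prof = backbone_torsions(model)
        a = block_torsion_summary(prof, blocks, stack)
        b = block_torsion_summary(prof, blocks, stack)
        assert a.equals(b)

    def test_exclusion_by_label(self, hybrid):
        model, _ = hybrid
        stack = tc.order_stack(
            tc.assemble_tetrads(tc.detect_hoogsteen_pairs(model)), model)
        steps = enumerate_gg_steps(model, stack)
        blocks = segment_blocks(steps, stack, model)
        prof = backbone_torsions(model)
        full = block_torsion_summary(prof, blocks, stack)
        # excluding one step residue label shrinks the contributing count
        excl = block_torsion_summary(prof, blocks, stack, exclusions=["G1"])
        n_full = full[(full.block == 0) & (full.angle == "chi")]["n"].iloc[0]
        n_excl = excl[(excl.block == 0) & (excl.angle == "chi")]["n"].iloc[0]
        assert n_excl < n_full
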