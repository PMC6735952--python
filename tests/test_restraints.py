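"""Restraint generation, NOE class table, validation and export."""

import importlib.resources as ir

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_rigid, transform_model
from g4kit import restraints as rst
from g4kit import synthetic as syn
from g4kit import tetrad_core as tc
from g4kit.structure_io import Atom, Residue, StructureModel


@pytest.fixture(scope="module")
def published_topology():
    path = ir.files("g4kit") / "data" / "tba_tt_block2.yaml"
    return rst.TopologySpec.from_yaml(str(path))


def _spec_from_stack(model):
    tetrads = tc.assemble_tetrads(tc.detect_hoogsteen_pairs(model))
    stack = tc.order_stack(tetrads, model)
    return rst.TopologySpec(
        tetrads=[[(r.chain_id, r.seq_number) for r in t.members]
                 for t in stack.tetrads],
        positions=[t.position for t in stack.tetrads],
        glycosidic={(r.chain_id, r.seq_number): "anti"
                    for t in stack.tetrads for r in t.members})


class TestBuilders:
    def test_four_tetrad_topology_counts(self, published_topology):
        rset = rst.build_restraints(published_topology)
        assert rset.counts == {"hbond": 64, "noe": 0, "dihedral": 16,
                               "planarity": 4}

    def test_one_tetrad_sixteen_hbonds(self):
        spec = rst.TopologySpec(tetrads=[[("A", 1), ("A", 5), ("A", 9), ("A", 13)]])
        assert len(rst.build_hbond_restraints(spec)) == 16
        assert len(rst.build_planarity_restraints(spec)) == 1

    def test_empty_spec_zero(self):
        spec = rst.TopologySpec()
        rset = rst.build_restraints(spec)
        assert sum(rset.counts.values()) == 0

    def test_duplicate_guanine_rejected(self):
        with pytest.raises(rst.TopologyError, match="appears in tetrads"):
            rst.TopologySpec(tetrads=[
                [("A", 1), ("A", 2), ("A", 3), ("A", 4)],
                [("A", 4), ("A", 5), ("A", 6), ("A", 7)]])

    def test_hbond_targets(self, published_topology):
        by_pair = {}
        for r in rst.build_hbond_restraints(published_topology):
            by_pair[(r.atom_a[2], r.atom_b[2])] = (r.target, r.minus, r.plus)
        assert by_pair[("H21", "N7")] == (2.0, 0.2, 0.2)
        assert by_pair[("N2", "N7")] == (2.9, 0.3, 0.3)
        assert by_pair[("H1", "O6")] == (2.0, 0.2, 0.2)
        assert by_pair[("N1", "O6")] == (2.9, 0.3, 0.3)

    def test_dihedral_widths_by_position(self, published_topology):
        widths = [r.width for r in rst.build_dihedral_restraints(published_topology)]
        assert widths.count(70.0) == 8 and widths.count(40.0) == 8
        assert all(r.center == 240.0
                   for r in rst.build_dihedral_restraints(published_topology))

    def test_syn_guanine_skipped(self):
        spec = rst.TopologySpec(
            tetrads=[[("A", 1), ("A", 2), ("A", 3), ("A", 4)]],
            positions=["outer"],
            glycosidic={("A", 1): "syn"})
        assert len(rst.build_dihedral_restraints(spec)) == 3

    @given(st.integers(min_value=0, max_value=6))
    @settings(max_examples=7, deadline=None)
    def test_counts_scale_linearly(self, n):
        tetrads = [[("A", 10 * i + j) for j in range(4)] for i in range(n)]
        spec = rst.TopologySpec(tetrads=tetrads,
                                positions=["outer"] * n)
        rset = rst.build_restraints(spec)
        assert rset.counts["hbond"] == 16 * n
        assert rset.counts["dihedral"] == 4 * n
        assert rset.counts["planarity"] == n


class TestNoeTable:
    @pytest.mark.parametrize("cls,exch,methyl,want", [
        ("strong", False, False, (2.7, 0.8, 0.8)),
        ("medium", False, False, (3.8, 0.9, 0.9)),
        ("medium-weak", False, False, (4.6, 1.2, 1.2)),
        ("weak", False, False, (5.5, 1.7, 1.7)),
        ("strong", True, False, (4.0, 1.2, 1.2)),
        ("medium", True, False, (4.8, 1.4, 1.4)),
        ("weak", True, False, (5.5, 1.7, 1.7)),
        ("strong", False, True, (4.0, 1.2, 1.2)),
        ("weak", False, True, (5.5, 2.2, 2.2)),
        ("weak", True, True, (5.5, 2.2, 2.2)),  # methyl overrides exchangeable
    ])
    def test_class_lookup(self, cls, exch, methyl, want):
        assert rst.classify_noe(cls, exch, methyl) == want

    def test_exchangeable_medium_weak_undefined(self):
        with pytest.raises(KeyError):
            rst.classify_noe("medium-weak", exchangeable=True)


class TestValidate:
    def test_generator_model_zero_violations(self, hybrid):
        model, _ = hybrid
        spec = _spec_from_stack(model)
        rep = rst.validate(model, rst.build_restraints(spec))
        assert rep["n_violations"] == 0
        assert rep["n_unevaluable"] == 0
        assert all(not flag for _, _, flag in rep["planarity_rms"])

    def test_stretched_n2_gives_exactly_one_violation(self, left_block2):
        base, _ = left_block2
        model = transform_model(base, np.eye(3), np.zeros(3))  # private copy
        spec = _spec_from_stack(model)
        rset = rst.build_restraints(spec)
        assert rst.validate(model, rset)["n_violations"] == 0
        # displace one donor's N2 so its N2–N7 distance becomes 4.0 Å
        target = rset.hbond[1]
        assert (target.atom_a[2], target.atom_b[2]) == ("N2", "N7")
        don = model.residue((target.atom_a[0], target.atom_a[1], ""))
        acc = model.residue((target.atom_b[0], target.atom_b[1], ""))
        n7 = acc.coord("N7")
        n2 = don.get_atom("N2")
        direction = (n2.coords - n7) / np.linalg.norm(n2.coords - n7)
        n2.coords = n7 + 4.0 * direction
        rep = rst.validate(model, rset)
        assert rep["n_violations"] == 1
        kind, r, dist, excess = rep["violations"][0]
        assert kind == "distance" and dist == pytest.approx(4.0)
        assert excess == pytest.approx(4.0 - (2.9 + 0.3 + 0.2), abs=1e-6)

    def test_missing_protons_unevaluable_not_violated(self, left_block2):
        model, _ = left_block2
        spec = _spec_from_stack(model)
        rset = rst.build_restraints(spec)
        stripped = StructureModel(1, [
            Residue(r.chain_id, r.seq_number, r.insertion_code, r.name,
                    [a for a in r.atoms if a.element != "H"], r.is_polymer)
            for r in model.residues])
        rep = rst.validate(stripped, rset)
        assert rep["n_violations"] == 0
        assert rep["n_unevaluable"] == 16  # H21–N7 and H1–O6 of 8 pairs

    def test_threshold_monotonicity(self, left_block2):
        model, _ = left_block2
        spec = _spec_from_stack(model)
        rset = rst.build_restraints(spec)
        noisy = syn.perturb(model, 0.35, 4)
        counts = [rst.validate(noisy, rset, violation_threshold=t)["n_violations"]
                  for t in (0.0, 0.1, 0.2, 0.5, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_rigid_motion_preserves_satisfaction(self, left_block2):
        model, _ = left_block2
        spec = _spec_from_stack(model)
        rset = rst.build_restraints(spec)
        rng = np.random.default_rng(3)
        R, t = random_rigid(rng)
        rep = rst.validate(transform_model(model, R, t), rset)
        assert rep["n_violations"] == 0


class TestExport:
    def test_xplor_has_one_assign_per_restraint(self, published_topology):
        rset = rst.build_restraints(published_topology)
        text = rst.export_restraints(rset, "xplor-tbl")
        assert sum(1 for l in text.splitlines()
                   if l.startswith("assign")) == 64 + 16

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            rst.export_restraints(rst.RestraintSet())

    def test_tsv_round_trip_counts(self, published_topology):
        rset = rst.build_restraints(published_topology)
        counts = rst.parse_restraints_tsv(rst.export_restraints(rset, "tsv"))
        assert counts == {"hbond": 64, "dihedral": 16, "planarity": 4}

    def test_noe_peaks_from_yaml(self):
        doc = """
name: toy
tetrads: [[G1, G2, G3, G4]]
positions: [outer]
all_anti: true
noe_peaks:
  - {from: G1, from_atom: "H1'", to: G2, to_atom: "H1'", class: strong}
  - {from: T5, from_atom: H6, to: G1, to_atom: H8, class: weak, methyl: true}
"""
        spec = rst.TopologySpec.from_yaml(doc)
        noe = rst.build_noe_restraints(spec)
        assert [(r.target, r.plus) for r in noe] == [(2.7, 0.8), (5.5, 2.2)]
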