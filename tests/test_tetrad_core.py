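"""Hoogsteen pair detection, tetrad assembly, stacking and polarity."""

import itertools

import numpy as np
import pytest

from conftest import mirror_model, random_rigid, transform_model
from g4kit import synthetic as syn
from g4kit import tetrad_core as tc
from g4kit.structure_io import StructureModel


def _analyze(model):
    pairs = tc.detect_hoogsteen_pairs(model)
    tetrads = tc.assemble_tetrads(pairs)
    return pairs, tetrads


class TestDetectPairs:
    def test_ideal_tetrad_four_directed_pairs_one_cycle(self, single_tetrad_model):
        pairs, tetrads = _analyze(single_tetrad_model)
        assert len(pairs) == 4
        # each guanine donates exactly once and accepts exactly once
        donors = [p.donor.key for p in pairs]
        acceptors = [p.acceptor.key for p in pairs]
        assert len(set(donors)) == 4 and len(set(acceptors)) == 4
        assert len(tetrads) == 1

    def test_two_guanines_at_hoogsteen_distance(self, single_tetrad_model):
        res = single_tetrad_model.residues
        # keep one donor/acceptor pair of the cycle
        pairs_all = tc.detect_hoogsteen_pairs(single_tetrad_model)
        don, acc = pairs_all[0].donor, pairs_all[0].acceptor
        model = StructureModel(model_id=1, residues=[don, acc])
        pairs = tc.detect_hoogsteen_pairs(model)
        assert len(pairs) == 1
        assert pairs[0].donor.key == don.key
        assert pairs[0].d_N2_N7 == pytest.approx(2.9, abs=0.15)
        assert pairs[0].d_N1_O6 == pytest.approx(2.9, abs=0.15)
        # proton distances reported since the model has hydrogens
        assert pairs[0].d_H21_N7 == pytest.approx(2.0, abs=0.3)
        assert pairs[0].d_H1_O6 == pytest.approx(2.0, abs=0.3)

    def test_translated_apart_no_pairs(self, single_tetrad_model):
        pairs_all = tc.detect_hoogsteen_pairs(single_tetrad_model)
        don, acc = pairs_all[0].donor, pairs_all[0].acceptor
        far = transform_model(StructureModel(1, [acc]), np.eye(3),
                              np.array([10.0, 0, 0])).residues[0]
        model = StructureModel(model_id=1, residues=[don, far])
        assert tc.detect_hoogsteen_pairs(model) == []

    def test_guanine_missing_heavy_atom_skipped(self, single_tetrad_model):
        residues = []
        for i, r in enumerate(single_tetrad_model.residues):
            if i == 0:
                r = type(r)(r.chain_id, r.seq_number, r.insertion_code, r.name,
                            [a for a in r.atoms if a.name != "O6"], r.is_polymer)
            residues.append(r)
        model = StructureModel(model_id=1, residues=residues)
        pairs = tc.detect_hoogsteen_pairs(model)
        # the crippled guanine is skipped; only pairs between the others remain
        assert all(p.donor.seq_number is not None for p in pairs)
        assert len(pairs) == 2  # 4-cycle loses the two edges touching it


class TestAssemble:
    def test_two_disjoint_cycles_two_tetrads(self, left_block2):
        model, truth = left_block2
        pairs, tetrads = _analyze(model)
        assert len(pairs) == 8
        assert len(tetrads) == 2
        got = sorted(sorted(t.member_keys) for t in tetrads)
        want = sorted(sorted(layer) for layer in truth.layers)
        assert got == want

    def test_empty_input_empty_output(self):
        assert tc.assemble_tetrads([]) == []

    def test_matches_bruteforce_4subset_oracle(self, hybrid):
        """Cycle search agrees with brute-force enumeration of 4-subsets."""
        model, _ = hybrid
        pairs = tc.detect_hoogsteen_pairs(model)
        edges = {(p.donor.key, p.acceptor.key) for p in pairs}
        guanines = sorted({p.donor.key for p in pairs}
                          | {p.acceptor.key for p in pairs})
        oracle_cycles = set()
        for quad in itertools.combinations(guanines, 4):
            for perm in itertools.permutations(quad):
                if perm[0] != min(perm):
                    continue
                cyc = list(perm) + [perm[0]]
                if all((cyc[i], cyc[i + 1]) in edges for i in range(4)):
                    oracle_cycles.add(frozenset(perm))
        got = {t.member_keys for t in tc.assemble_tetrads(pairs)}
        assert got <= oracle_cycles
        # here no overlaps exist, so greedy keeps every brute-force cycle
        assert got == oracle_cycles


class TestStack:
    def test_four_layers_ordered_with_positions(self, right_block4):
        model, truth = right_block4
        _, tetrads = _analyze(model)
        stack = tc.order_stack(tetrads, model)
        assert [t.layer_index for t in stack.tetrads] == [0, 1, 2, 3]
        assert [t.position for t in stack.tetrads] == \
            ["outer", "inner", "inner", "outer"]
        got_layers = [sorted(t.member_keys) for t in stack.tetrads]
        assert got_layers == [sorted(l) for l in truth.layers]

    def test_single_tetrad_outer_layer_zero(self, single_tetrad_model):
        _, tetrads = _analyze(single_tetrad_model)
        stack = tc.order_stack(tetrads, single_tetrad_model)
        assert stack.tetrads[0].layer_index == 0
        assert stack.tetrads[0].position == "outer"

    def test_two_layers_both_outer(self, left_block2):
        model, _ = left_block2
        _, tetrads = _analyze(model)
        stack = tc.order_stack(tetrads, model)
        assert [t.position for t in stack.tetrads] == ["outer", "outer"]

    def test_rise_recovered_from_centroids(self, right_block4):
        model, truth = right_block4
        _, tetrads = _analyze(model)
        stack = tc.order_stack(tetrads, model)
        seps = [float(np.dot(b.centroid - a.centroid, stack.axis))
                for a, b in zip(stack.tetrads, stack.tetrads[1:])]
        assert np.allclose(seps, truth.rise, atol=0.05)


class TestPolarity:
    def test_requested_polarity_built_and_detected(self):
        for want in ("clockwise", "anticlockwise"):
            model = StructureModel(1, syn.build_tetrad(want))
            _, tetrads = _analyze(model)
            assert tc.tetrad_polarity(tetrads[0], np.array([0, 0, 1.0])) == want

    def test_axis_negation_flips(self, single_tetrad_model):
        _, tetrads = _analyze(single_tetrad_model)
        up = tc.tetrad_polarity(tetrads[0], np.array([0, 0, 1.0]))
        dn = tc.tetrad_polarity(tetrads[0], np.array([0, 0, -1.0]))
        assert {up, dn} == {"clockwise", "anticlockwise"}

    def test_mirror_flips_polarity(self, single_tetrad_model):
        _, tetrads = _analyze(single_tetrad_model)
        pol = tc.tetrad_polarity(tetrads[0], np.array([0, 0, 1.0]))
        mirrored = mirror_model(single_tetrad_model)
        _, tets_m = _analyze(mirrored)
        pol_m = tc.tetrad_polarity(tets_m[0], np.array([0, 0, 1.0]))
        assert pol != pol_m

    def test_rigid_motion_invariance(self, right_block4):
        model, truth = right_block4
        rng = np.random.default_rng(11)
        want = sorted(sorted(l) for l in truth.layers)
        for _ in range(5):
            R, t = random_rigid(rng)
            moved = transform_model(model, R, t)
            _, tetrads = _analyze(moved)
            assert sorted(sorted(t_.member_keys) for t_ in tetrads) == want
            stack = tc.order_stack(tetrads, moved)
            assert [t_.polarity for t_ in stack.tetrads] == ["clockwise"] * 4


class TestExchangeProtection:
    def test_four_layers_inner_protected(self, right_block4):
        model, _ = right_block4
        _, tetrads = _analyze(model)
        stack = tc.order_stack(tetrads, model)
        part = tc.predict_exchange_protection(stack)
        prot = {r.seq_number for r in part["protected"]}
        exch = {r.seq_number for r in part["exchanging"]}
        assert prot == {2, 3} and exch == {1, 4}

    def test_two_layers_all_exchanging(self, left_block2):
        model, _ = left_block2
        _, tetrads = _analyze(model)
        stack = tc.order_stack(tetrads, model)
        part = tc.predict_exchange_protection(stack)
        assert part["protected"] == []
        assert len(part["exchanging"]) == 8

    def test_three_layers_middle_protected(self):
        model, _ = syn.build_block(syn.BlockSpec(3, "right", 30.0))
        _, tetrads = _analyze(model)
        stack = tc.order_stack(tetrads, model)
        part = tc.predict_exchange_protection(stack)
        assert {r.seq_number for r in part["protected"]} == {2}


def test_recovery_under_jitter_sd02_50_seeds(right_block4):
    """Membership recovery stays perfect at coordinate jitter sd 0.2 Å."""
    model, truth = right_block4
    want = sorted(sorted(l) for l in truth.layers)
    for seed in range(50):
        noisy = syn.perturb(model, 0.2, seed)
        tetrads = tc.assemble_tetrads(tc.detect_hoogsteen_pairs(noisy))
        assert sorted(sorted(t.member_keys) for t in tetrads) == want, seed
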