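"""Shared fixtures: synthetic structures with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from g4kit import synthetic as syn
from g4kit.structure_io import Atom, Residue, StructureModel


@pytest.fixture(scope="session")
def right_block4():
    """Four-layer right-handed parallel block with ground truth."""
    return syn.build_block(syn.BlockSpec(4, "right", 30.0))


@pytest.fixture(scope="session")
def left_block2():
    return syn.build_block(syn.BlockSpec(2, "left", -30.0))


@pytest.fixture(scope="session")
def hybrid():
    """Left block below, right block above, 5′-5′-type junction."""
    spec = syn.SyntheticG4Spec(
        blocks=[syn.BlockSpec(2, "left", -30.0), syn.BlockSpec(2, "right", 30.0)],
        junction_mode="five-prime-five-prime")
    return syn.build_hybrid(spec)


@pytest.fixture(scope="session")
def single_tetrad_model():
    residues = syn.build_tetrad("clockwise")
    return StructureModel(model_id=1, residues=residues)


def transform_model(model: StructureModel, R: np.ndarray,
                    t: np.ndarray) -> StructureModel:
    """Apply x → R x + t to every atom (R need not be proper)."""
    residues = []
    for res in model.residues:
        atoms = [Atom(a.name, a.element, R @ a.coords + t,
                      a.occupancy, a.bfactor, a.altloc) for a in res.atoms]
        residues.append(Residue(res.chain_id, res.seq_number,
                                res.insertion_code, res.name, atoms,
                                res.is_polymer))
    return StructureModel(model_id=model.model_id, residues=residues)


def mirror_model(model: StructureModel) -> StructureModel:
    """Coordinate mirror (x → −x): inverts chirality."""
    return transform_model(model, np.diag([-1.0, 1.0, 1.0]), np.zeros(3))


def random_rigid(rng) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.normal(scale=20.0, size=3)
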