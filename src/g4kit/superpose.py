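"""Least-squares superposition and ensemble RMSD statistics.

Optimal rigid-body superposition is computed by the SVD (Kabsch) method
with reflections excluded, so chirality is never silently inverted.
Ensemble statistics follow the NMR convention: every unordered model pair
is superposed on a named atom selection (optionally minus an exclusion
list) and the mean ± sample standard deviation of the pairwise RMSDs is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch
from .structure_io import Ensemble, StructureModel, coords_of, select_atoms

__all__ = ["SuperpositionResult", "superpose", "superpose_models",
           "ensemble_pairwise_rmsd", "matched_coords"]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    selection: str = ""

    def __post_init__(self):
        assert self.rmsd >= -1e-12
        assert abs(np.linalg.det(self.rotation) - 1.0) < 1e-6


def superpose(coords_a: np.ndarray, coords_b: np.ndarray,
              selection: str = "") -> SuperpositionResult:
    """Optimal proper-rotation superposition of two matched coordinate sets.

    Returns the rotation/translation carrying ``coords_a`` onto ``coords_b``
    and the minimized RMSD. Correspondence is positional; use
    :func:`matched_coords` to build matched lists from models.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate shapes differ: {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 matched atoms")
    R, t, rmsd = kabsch(A, B)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=A.shape[0], selection=selection)


def matched_coords(model_a: StructureModel, model_b: StructureModel,
                   selection: str = "heavy",
                   exclusions: list | None = None,
                   residues: list | None = None):
    """Matched coordinate arrays for two models by (residue key, atom name).

    Raises a correspondence error listing unmatched keys when the selected
    atom sets differ.
    """
    sel_kw: dict = {}
    if exclusions:
        pairs_a = select_atoms(model_a, "exclude-residues", residues=exclusions)
        pairs_b = select_atoms(model_b, "exclude-residues", residues=exclusions)
        if selection != "heavy":
            raise ValueError("exclusions are applied to the heavy selection")
    else:
        pairs_a = select_atoms(model_a, selection, residues=residues, **sel_kw)
        pairs_b = select_atoms(model_b, selection, residues=residues, **sel_kw)
    keyed_a = {(r.key, a.name): a.coords for r, a in pairs_a}
    keyed_b = {(r.key, a.name): a.coords for r, a in pairs_b}
    common = sorted(set(keyed_a) & set(keyed_b))
    only_a = set(keyed_a) - set(keyed_b)
    only_b = set(keyed_b) - set(keyed_a)
    if only_a or only_b:
        raise ValueError(
            "atom correspondence mismatch; unmatched keys: "
            f"{sorted(only_a)[:5]} / {sorted(only_b)[:5]}")
    A = np.array([keyed_a[k] for k in common])
    B = np.array([keyed_b[k] for k in common])
    return A, B


def superpose_models(model_a: StructureModel, model_b: StructureModel,
                     selection: str = "heavy",
                     exclusions: list | None = None,
                     residues: list | None = None) -> SuperpositionResult:
    A, B = matched_coords(model_a, model_b, selection, exclusions, residues)
    return superpose(A, B, selection=selection)


def ensemble_pairwise_rmsd(ensemble: Ensemble, selection: str = "heavy",
                           exclusions: list | None = None,
                           residues: list | None = None):
    """Mean, sample sd and matrix of all-pairs RMSDs over an ensemble.

    Requires a shared-topology ensemble of at least two models; the
    selection (minus exclusions) must be non-empty.
    """
    models = ensemble.models
    if len(models) < 2:
        raise ValueError("need at least 2 models for pairwise RMSD")
    if not ensemble.shared_topology:
        raise ValueError("ensemble models do not share a topology")
    n = len(models)
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            res = superpose_models(models[i], models[j], selection,
                                   exclusions, residues)
            if res.n_atoms == 0:
                raise ValueError("empty selection after exclusions")
            mat[i, j] = mat[j, i] = res.rmsd
            vals.append(res.rmsd)
    vals = np.array(vals)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd, mat
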