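"""Per-step helical handedness, block segmentation and junction analysis.

The handedness of a guanine–guanine (GG) step is read from the angle between
two vectors: the C5′→C3′ vector of the 5′ residue's sugar (the local sugar
orientation) and the vector from the 5′ residue's tetrad centroid to the 3′
residue's tetrad centroid (the backbone progression). In a right-handed GG
step the two vectors are less than 90° apart; in a left-handed step more
than 90°. Maximal runs of layers whose steps agree form handedness-uniform
blocks, and the interface between adjacent blocks is characterized by the
relative cyclic polarity of the two interface tetrads, their inter-block
sugar–sugar (C1′/H1′) contacts, and the 5/6-ring stacking mode.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (DegenerateGeometryError, angle_between, fit_plane,
                       kabsch, unit)
from .structure_io import Residue, StructureModel
from .tetrad_core import Tetrad, TetradStack, _ring_centroid

logger = logging.getLogger(__name__)

__all__ = [
    "GGStep", "G4Block", "Junction",
    "enumerate_gg_steps", "classify_step", "segment_blocks", "detect_junction",
    "step_table", "block_table", "junction_table",
]

#: half-width (degrees) of the ambiguous band around 90°
ANGLE_EPSILON = 1.0

_RING5 = ["N9", "C8", "N7", "C5", "C4"]
_RING6 = ["N1", "C2", "N3", "C4", "C5", "C6"]

# The sugar/progression angle rule is calibrated for D-deoxyribose: the two
# vectors are mirrored together by a reflection, so the angle alone cannot
# sense chirality. The classifier therefore also determines the enantiomer
# of the 5' sugar — by superposing the idealized D-deoxyribose fragment and
# its mirror image onto the observed sugar atoms and keeping the better fit
# — and swaps the call for L-sugars, so that a mirrored structure is
# reported with the handedness it actually has.
_SUGAR_FRAME_ATOMS = ["C1'", "C2'", "C3'", "C4'", "O4'", "C5'", "O3'", "N9"]


def _sugar_reference() -> dict[str, np.ndarray]:
    from ._ideal_guanine import full_template
    tmpl = full_template()
    return {n: tmpl[n] for n in _SUGAR_FRAME_ATOMS}


_SUGAR_REF = _sugar_reference()
_MIRROR = np.diag([-1.0, 1.0, 1.0])


def sugar_enantiomer(res: Residue) -> str | None:
    """'D' or 'L' by enantiomer-resolved template fitting.

    Superposes the ideal D-sugar fragment and its mirror image onto the
    observed sugar atoms (proper rotations only); the enantiomer is the one
    fitting with the lower RMSD. None when fewer than four fragment atoms
    are present or the fits are indistinguishable.
    """
    names = [n for n in _SUGAR_FRAME_ATOMS if res.coord(n) is not None]
    if len(names) < 4:
        return None
    obs = np.array([res.coord(n) for n in names])
    ref = np.array([_SUGAR_REF[n] for n in names])
    _, _, rmsd_d = kabsch(ref, obs)
    _, _, rmsd_l = kabsch(ref @ _MIRROR, obs)
    if abs(rmsd_d - rmsd_l) < 1e-3:
        return None
    return "D" if rmsd_d < rmsd_l else "L"


@dataclass
class GGStep:
    res_5p: Residue
    res_3p: Residue
    layer_5p: int
    layer_3p: int
    sugar_vector: np.ndarray | None
    progression_vector: np.ndarray
    angle: float | None
    call: str                      # {right, left, ambiguous}
    sugar_chirality: str = "D"     # enantiomer of the 5' sugar

    @property
    def label(self) -> str:
        return f"{self.res_5p.chain_id}/{self.res_5p.label}-{self.res_3p.label}"


@dataclass
class G4Block:
    layers: list[int]
    handedness: str | None         # {right, left} or None for a lone layer
    steps: list[GGStep] = field(default_factory=list)
    strand_polarity: str | None = None   # {parallel, antiparallel, hybrid}


@dataclass
class Junction:
    block_a: G4Block
    block_b: G4Block
    interface: tuple[Tetrad, Tetrad]
    polarity_relation: str         # {same, opposite}
    sugar_contacts: list[tuple]    # (res_a, res_b, d_C1, d_H1 or None)
    stacking_modes: dict           # (key_a, key_b) → "5/6" style mode


def classify_step(step: GGStep, epsilon: float = ANGLE_EPSILON) -> str:
    """Handedness call from the sugar/progression angle.

    ``right`` below 90°−ε, ``left`` above 90°+ε, else ``ambiguous`` — for a
    D-sugar step; the call is swapped when the 5′ sugar is the L-enantiomer
    (``step.sugar_chirality``), so reflections report flipped handedness.
    """
    if step.sugar_vector is None:
        return "ambiguous"
    ang = angle_between(step.sugar_vector, step.progression_vector)
    step.angle = ang
    if ang < 90.0 - epsilon:
        call = "right"
    elif ang > 90.0 + epsilon:
        call = "left"
    else:
        return "ambiguous"
    if step.sugar_chirality == "L":
        call = {"right": "left", "left": "right"}[call]
    return call


def enumerate_gg_steps(model: StructureModel, stack: TetradStack,
                       epsilon: float = ANGLE_EPSILON) -> list[GGStep]:
    """All GG steps: sequence-adjacent core guanines in adjacent layers.

    The sugar vector is taken from the 5′ residue (the sugar at the layer
    the progression vector leaves); steps with missing C5′/C3′ atoms are
    emitted with an ``ambiguous`` call and a warning.
    """
    layer_of = {}
    tetrad_of = {}
    for t in stack.tetrads:
        for r in t.members:
            layer_of[r.key] = t.layer_index
            tetrad_of[r.key] = t
    core = [r for r in model.guanines() if r.key in layer_of]
    by_chain: dict[str, list[Residue]] = {}
    for r in core:
        by_chain.setdefault(r.chain_id, []).append(r)
    steps: list[GGStep] = []
    for chain in sorted(by_chain):
        strand = sorted(by_chain[chain], key=lambda r: (r.seq_number, r.insertion_code))
        for r5, r3 in zip(strand, strand[1:]):
            l5, l3 = layer_of[r5.key], layer_of[r3.key]
            if abs(l3 - l5) != 1:
                continue
            prog = tetrad_of[r3.key].centroid - tetrad_of[r5.key].centroid
            c5, c3 = r5.coord("C5'"), r5.coord("C3'")
            if c5 is None or c3 is None:
                logger.warning("step %s/%s-%s lacks sugar atoms; ambiguous",
                               chain, r5.label, r3.label)
                step = GGStep(r5, r3, l5, l3, None, prog, None, "ambiguous")
            else:
                chirality = sugar_enantiomer(r5) or "D"
                step = GGStep(r5, r3, l5, l3, c3 - c5, prog, None, "",
                              sugar_chirality=chirality)
                step.call = classify_step(step, epsilon)
            steps.append(step)
    return steps


def _strand_polarity(layers: list[int], stack: TetradStack,
                     model: StructureModel) -> str | None:
    """Parallel / antiparallel / hybrid from strand directions vs the axis."""
    layer_set = set(layers)
    members: dict[str, list[Residue]] = {}
    for t in stack.tetrads:
        if t.layer_index in layer_set:
            for r in t.members:
                members.setdefault(r.chain_id, []).append(r)
    signs = []
    for chain, rs in members.items():
        rs = sorted(rs, key=lambda r: (r.seq_number, r.insertion_code))
        if len(rs) < 2:
            continue
        d = _ring_centroid(rs[-1]) - _ring_centroid(rs[0])
        signs.append(np.sign(float(np.dot(d, stack.axis))))
    if not signs:
        return None
    n_up = sum(1 for s in signs if s > 0)
    if n_up == len(signs) or n_up == 0:
        return "parallel"
    if abs(n_up - len(signs) / 2) < 1:
        return "antiparallel"
    return "hybrid"


def segment_blocks(steps: list[GGStep], stack: TetradStack,
                   model: StructureModel | None = None) -> list[G4Block]:
    """Segment the stack into maximal handedness-uniform blocks.

    The call joining layers l and l+1 is the majority over the (≤4) steps
    bridging them; ties, ambiguous calls or absent steps break blocks.
    """
    n = len(stack.tetrads)
    joins: list[str | None] = []
    for l in range(n - 1):
        bridging = [s.call for s in steps
                    if {s.layer_5p, s.layer_3p} == {l, l + 1}]
        counts = Counter(c for c in bridging if c in ("right", "left"))
        if not counts:
            joins.append(None)
            continue
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            logger.warning("conflicting handedness between layers %d and %d; "
                           "treated as a block boundary", l, l + 1)
            joins.append(None)
        else:
            joins.append(top[0][0])
    # a block is a maximal run of layers linked by joins of one call; a None
    # join (absent/ambiguous/tied steps) or a call change is a boundary, and
    # the boundary-crossing join belongs to neither block
    blocks: list[G4Block] = []
    current_layers = [0]
    current_call: str | None = None
    for l in range(n - 1):
        j = joins[l]
        if j is not None and (current_call is None or j == current_call):
            current_call = j
            current_layers.append(l + 1)
        else:
            blocks.append(G4Block(layers=current_layers, handedness=current_call))
            current_layers = [l + 1]
            current_call = None
    blocks.append(G4Block(layers=current_layers, handedness=current_call))
    # attach steps and strand polarity
    for b in blocks:
        lset = set(b.layers)
        b.steps = [s for s in steps if s.layer_5p in lset and s.layer_3p in lset]
        if model is not None:
            b.strand_polarity = _strand_polarity(b.layers, stack, model)
    return blocks


def _ring_mid(res: Residue, names: list[str]) -> np.ndarray | None:
    pts = [res.coord(n) for n in names]
    if any(p is None for p in pts):
        return None
    return np.mean(pts, axis=0)


def _stacking_mode(upper: Residue, lower: Residue, max_lateral: float = 2.5) -> str:
    """5/6-ring stacking assignment: project the upper guanine's ring
    centroids onto the lower base plane and take the laterally nearest
    partner ring within ``max_lateral`` Å ("upper/lower" ring order)."""
    ring_atoms = sorted(set(_RING5 + _RING6))
    pts = [lower.coord(n) for n in ring_atoms]
    if any(p is None for p in pts):
        return "none"
    centre, normal = fit_plane(np.array(pts))
    best = None
    for uname, uring in (("5", _RING5), ("6", _RING6)):
        cu = _ring_mid(upper, uring)
        if cu is None:
            continue
        cu_proj = cu - np.dot(cu - centre, normal) * normal
        for lname, lring in (("5", _RING5), ("6", _RING6)):
            cl = _ring_mid(lower, lring)
            if cl is None:
                continue
            d = float(np.linalg.norm(cu_proj - cl))
            if best is None or d < best[0]:
                best = (d, f"{uname}/{lname}")
    if best is None or best[0] > max_lateral:
        return "none"
    return best[1]


def detect_junction(blocks: list[G4Block], stack: TetradStack,
                    model: StructureModel,
                    contact_cutoff_c1: float = 5.5,
                    contact_cutoff_h1: float = 4.0) -> list[Junction]:
    """Characterize every adjacent block–block interface.

    Reports the relative cyclic polarity of the two interface tetrads (both
    viewed along the common stack axis), the inter-block sugar contacts
    (greedy nearest-neighbour C1′–C1′ pairing under the cutoff, H1′–H1′
    reported when protons exist) and the per-pair ring stacking mode.
    """
    if len(blocks) < 2:
        return []
    tet_by_layer = {t.layer_index: t for t in stack.tetrads}
    junctions = []
    for ba, bb in zip(blocks, blocks[1:]):
        t_low = tet_by_layer[max(ba.layers)]
        t_up = tet_by_layer[min(bb.layers)]
        relation = "same" if t_low.polarity == t_up.polarity else "opposite"
        cands = []
        for ru in t_up.members:
            cu = ru.coord("C1'")
            if cu is None:
                continue
            for rl in t_low.members:
                cl = rl.coord("C1'")
                if cl is None:
                    continue
                cands.append((float(np.linalg.norm(cu - cl)), ru, rl))
        cands.sort(key=lambda x: (x[0], x[1].key, x[2].key))
        used_u, used_l = set(), set()
        contacts = []
        modes = {}
        for d, ru, rl in cands:
            if d > contact_cutoff_c1 or ru.key in used_u or rl.key in used_l:
                continue
            used_u.add(ru.key)
            used_l.add(rl.key)
            h_u, h_l = ru.coord("H1'"), rl.coord("H1'")
            dh = (float(np.linalg.norm(h_u - h_l))
                  if h_u is not None and h_l is not None else None)
            contacts.append((ru, rl, d, dh))
            modes[(ru.key, rl.key)] = _stacking_mode(ru, rl)
        if not contacts:
            logger.warning("no inter-block sugar contacts under %.1f Å",
                           contact_cutoff_c1)
        contacts.sort(key=lambda c: (c[0].key, c[1].key))
        junctions.append(Junction(
            block_a=ba, block_b=bb, interface=(t_low, t_up),
            polarity_relation=relation, sugar_contacts=contacts,
            stacking_modes=modes))
    return junctions


# ---------------------------------------------------------------------------
# reporting

def step_table(steps: list[GGStep]) -> pd.DataFrame:
    return pd.DataFrame([{
        "step": s.label,
        "layer_5p": s.layer_5p,
        "layer_3p": s.layer_3p,
        "angle": None if s.angle is None else round(s.angle, 2),
        "call": s.call,
    } for s in steps])


def block_table(blocks: list[G4Block]) -> pd.DataFrame:
    return pd.DataFrame([{
        "layers": "-".join(map(str, b.layers)),
        "handedness": b.handedness,
        "n_steps": len(b.steps),
        "strand_polarity": b.strand_polarity,
    } for b in blocks])


def junction_table(junctions: list[Junction]) -> pd.DataFrame:
    rows = []
    for j in junctions:
        for ru, rl, dc1, dh1 in j.sugar_contacts:
            rows.append({
                "interface": f"{j.interface[0].name} | {j.interface[1].name}",
                "polarity_relation": j.polarity_relation,
                "pair": f"{ru.chain_id}/{ru.label}-{rl.chain_id}/{rl.label}",
                "d_C1_C1": round(dc1, 3),
                "d_H1_H1": None if dh1 is None else round(dh1, 3),
                "stacking": j.stacking_modes.get((ru.key, rl.key)),
            })
        if not j.sugar_contacts:
            rows.append({
                "interface": f"{j.interface[0].name} | {j.interface[1].name}",
                "polarity_relation": j.polarity_relation,
                "pair": None, "d_C1_C1": None, "d_H1_H1": None,
                "stacking": None,
            })
    return pd.DataFrame(rows)
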