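"""Backbone and glycosidic torsion angles with per-block circular summaries.

Backbone angles follow the standard nucleic-acid definitions::

    α: O3'(i−1)–P–O5'–C5'      δ: C5'–C4'–C3'–O3'
    β: P–O5'–C5'–C4'           ε: C4'–C3'–O3'–P(i+1)
    γ: O5'–C5'–C4'–C3'         ζ: C3'–O3'–P(i+1)–O5'(i+1)

and the purine glycosidic angle χ is O4'–C1'–N9–C4. Backbone angles are
reported on (−180, 180]; χ on [0, 360), the convention in which the anti
window is written 240 ± 70°. Angles whose defining atoms are missing are
absent (None), never zero. Summaries use circular (vector-mean) statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import circular_mean_sd, dihedral
from .structure_io import Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionProfile", "backbone_torsions", "classify_glycosidic",
    "block_torsion_summary", "torsion_table", "to_0_360", "to_pm180",
]

BACKBONE_ANGLES = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
ALL_ANGLES = BACKBONE_ANGLES + ["chi"]

#: anti window in the 0–360 χ convention (closed interval, 240 ± 70)
ANTI_WINDOW = (170.0, 310.0)
#: syn band in the 0–360 χ convention (half-open)
SYN_WINDOW = (0.0, 120.0)


def to_0_360(angle: float) -> float:
    return angle % 360.0


def to_pm180(angle: float) -> float:
    a = angle % 360.0
    return a - 360.0 if a > 180.0 else a


@dataclass
class TorsionProfile:
    """Per-residue torsion angles for one model."""
    angles: dict = field(default_factory=dict)      # res key → {name: float|None}
    glycosidic: dict = field(default_factory=dict)  # res key → {syn, anti, undefined}
    labels: dict = field(default_factory=dict)      # res key → residue label

    def of(self, key, name: str) -> float | None:
        return self.angles.get(key, {}).get(name)


def _quartet(defs, res_prev, res, res_next):
    """Resolve an angle's four atoms across residues i−1, i, i+1."""
    pts = []
    for offset, name in defs:
        r = {-1: res_prev, 0: res, +1: res_next}[offset]
        p = r.coord(name) if r is not None else None
        if p is None:
            return None
        pts.append(p)
    return pts


_ANGLE_DEFS = {
    "alpha": [(-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")],
    "beta": [(0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")],
    "gamma": [(0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")],
    "delta": [(0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")],
    "epsilon": [(0, "C4'"), (0, "C3'"), (0, "O3'"), (+1, "P")],
    "zeta": [(0, "C3'"), (0, "O3'"), (+1, "P"), (+1, "O5'")],
    "chi": [(0, "O4'"), (0, "C1'"), (0, "N9"), (0, "C4")],
}


def backbone_torsions(model: StructureModel) -> TorsionProfile:
    """Torsion profile of every polymer residue of a model.

    Chain neighbours are the sequence-adjacent residues of the same chain;
    5′-terminal residues have no α and 3′-terminal residues no ε/ζ. χ is
    computed for purines (N9/C4 present).
    """
    profile = TorsionProfile()
    by_chain: dict[str, list[Residue]] = {}
    for r in model.polymer_residues():
        by_chain.setdefault(r.chain_id, []).append(r)
    for chain, residues in by_chain.items():
        residues = sorted(residues, key=lambda r: (r.seq_number, r.insertion_code))
        for i, res in enumerate(residues):
            prev_r = residues[i - 1] if i > 0 else None
            next_r = residues[i + 1] if i < len(residues) - 1 else None
            if prev_r is not None and prev_r.seq_number + 1 != res.seq_number:
                prev_r = None
            if next_r is not None and res.seq_number + 1 != next_r.seq_number:
                next_r = None
            entry = {}
            for name, defs in _ANGLE_DEFS.items():
                pts = _quartet(defs, prev_r, res, next_r)
                if pts is None:
                    entry[name] = None
                    continue
                ang = dihedral(*pts)
                entry[name] = to_0_360(ang) if name == "chi" else ang
            profile.angles[res.key] = entry
            profile.labels[res.key] = res.label
            chi = entry["chi"]
            profile.glycosidic[res.key] = (
                "undefined" if chi is None else classify_glycosidic(chi))
    return profile


def classify_glycosidic(chi: float) -> str:
    """syn/anti classification of a χ value (degrees, any convention).

    anti for χ ∈ [170, 310] (the 240 ± 70 anti window, closed); syn for
    χ ∈ [0, 120); otherwise undefined.
    """
    c = to_0_360(chi)
    if ANTI_WINDOW[0] <= c <= ANTI_WINDOW[1]:
        return "anti"
    if SYN_WINDOW[0] <= c < SYN_WINDOW[1]:
        return "syn"
    return "undefined"


def block_torsion_summary(profile: TorsionProfile, blocks, stack,
                          exclusions: list | None = None) -> pd.DataFrame:
    """Circular mean/sd of each torsion over each block's step residues.

    ``exclusions`` lists residue keys or labels to drop (divergent steps).
    Blocks with no contributing residues after exclusions are absent from
    the output (with a warning).
    """
    excl = set()
    for e in exclusions or []:
        if isinstance(e, tuple):
            excl.add(e)
        else:
            excl.update(k for k, lab in profile.labels.items() if lab == e)
    rows = []
    for bi, block in enumerate(blocks):
        keys = set()
        for s in block.steps:
            keys.add(s.res_5p.key)
            keys.add(s.res_3p.key)
        if not block.steps:
            layer_set = set(block.layers)
            for t in stack.tetrads:
                if t.layer_index in layer_set:
                    keys |= {r.key for r in t.members}
        keys -= excl
        if not keys:
            logger.warning("block %d has no residues after exclusions", bi)
            continue
        for name in ALL_ANGLES:
            vals = [profile.of(k, name) for k in sorted(keys)]
            vals = [v for v in vals if v is not None]
            if not vals:
                continue
            mean, sd = circular_mean_sd(vals)
            if name == "chi":
                mean = to_0_360(mean)
            rows.append({
                "block": bi,
                "handedness": block.handedness,
                "angle": name,
                "n": len(vals),
                "circular_mean": round(mean, 2),
                "circular_sd": round(sd, 2),
            })
    return pd.DataFrame(rows)


def torsion_table(profile: TorsionProfile) -> pd.DataFrame:
    rows = []
    for key in sorted(profile.angles):
        entry = profile.angles[key]
        row = {"chain": key[0], "residue": profile.labels[key]}
        for name in ALL_ANGLES:
            v = entry.get(name)
            row[name] = None if v is None else round(v, 2)
        row["glycosidic"] = profile.glycosidic[key]
        rows.append(row)
    return pd.DataFrame(rows)
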