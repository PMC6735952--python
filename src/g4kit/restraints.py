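"""NMR restraint engine: declarative topology in, restraint records out.

A :class:`TopologySpec` states the experimentally derived topology of a
G-quadruplex — tetrad membership in cyclic donor→acceptor order, outer/inner
layer positions, per-guanine glycosidic assignment, and the assigned NOE
peak list — and the builders expand it into enumerable restraint records:

* Hoogsteen hydrogen bonds: per directed G•G pair, H21–N7 2.0 ± 0.2 Å,
  N2–N7 2.9 ± 0.3 Å, H1–O6 2.0 ± 0.2 Å and N1–O6 2.9 ± 0.3 Å
  (4 restraints × 4 pairs × tetrad).
* χ dihedrals: one O4′–C1′–N9–C4 restraint per anti core guanine, centred
  at 240° with half-width 70° (outer tetrad) or 40° (inner tetrad).
* Planarity: one group per tetrad (force constant 1 kcal mol⁻¹ Å⁻²
  recorded as annotation).
* NOE distances from the class table (strong/medium/medium-weak/weak for
  non-exchangeable, strong/medium/weak for exchangeable and methyl).

Restraint bounds are flat-bottom wells [target−minus, target+plus]; a model
violates a distance restraint when the distance leaves the well by more
than the violation threshold (0.2 Å by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geometry import circular_distance, dihedral, fit_plane
from .structure_io import StructureModel

__all__ = [
    "TopologySpec", "DistanceRestraint", "DihedralRestraint",
    "PlanarityRestraint", "RestraintSet", "NOE_CLASS_TABLE",
    "build_hbond_restraints", "build_dihedral_restraints",
    "build_planarity_restraints", "build_noe_restraints", "build_restraints",
    "classify_noe", "validate", "export_restraints", "parse_restraints_tsv",
    "TopologyError",
]


class TopologyError(ValueError):
    pass


#: NOE class → (target, minus, plus) in Å, keyed by category
NOE_CLASS_TABLE = {
    "non-exchangeable": {
        "strong": (2.7, 0.8, 0.8),
        "medium": (3.8, 0.9, 0.9),
        "medium-weak": (4.6, 1.2, 1.2),
        "weak": (5.5, 1.7, 1.7),
    },
    "exchangeable": {
        "strong": (4.0, 1.2, 1.2),
        "medium": (4.8, 1.4, 1.4),
        "weak": (5.5, 1.7, 1.7),
    },
    "methyl": {
        "strong": (4.0, 1.2, 1.2),
        "medium": (4.8, 1.4, 1.4),
        "weak": (5.5, 2.2, 2.2),
    },
}

#: Hoogsteen restraint template per directed donor→acceptor pair:
#: (donor atom, acceptor atom, target, minus, plus)
HOOGSTEEN_RESTRAINTS = [
    ("H21", "N7", 2.0, 0.2, 0.2),
    ("N2", "N7", 2.9, 0.3, 0.3),
    ("H1", "O6", 2.0, 0.2, 0.2),
    ("N1", "O6", 2.9, 0.3, 0.3),
]

CHI_CENTER = 240.0
CHI_WIDTH = {"outer": 70.0, "inner": 40.0}
PLANARITY_WEIGHT = 1.0      # kcal mol^-1 Å^-2, annotation only
PLANARITY_RMS_THRESHOLD = 0.5   # Å, reporting threshold for group planarity


AtomRef = tuple[str, int, str]   # (chain, residue number, atom name)


def _parse_ref(text: str, default_chain: str = "A") -> tuple[str, int]:
    """'G2' or 'B/G2' → (chain, seq number)."""
    chain = default_chain
    if "/" in text:
        chain, text = text.split("/", 1)
    digits = "".join(ch for ch in text if ch.isdigit() or ch == "-")
    if not digits:
        raise TopologyError(f"cannot parse residue reference {text!r}")
    return chain, int(digits)


@dataclass
class TopologySpec:
    """Declarative G4 topology (tetrads, positions, glycosidic, NOE peaks)."""
    tetrads: list[list[tuple[str, int]]] = field(default_factory=list)
    positions: list[str] = field(default_factory=list)        # per tetrad
    glycosidic: dict = field(default_factory=dict)            # (chain, num) → syn/anti
    noe_peaks: list[dict] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self):
        seen = {}
        for i, tet in enumerate(self.tetrads):
            if len(tet) != 4:
                raise TopologyError(f"tetrad {i} does not have 4 members")
            for ref in tet:
                if ref in seen:
                    raise TopologyError(
                        f"guanine {ref} appears in tetrads {seen[ref]} and {i}")
                seen[ref] = i
        if self.positions and len(self.positions) != len(self.tetrads):
            raise TopologyError("positions must match the number of tetrads")
        for p in self.positions:
            if p not in ("outer", "inner"):
                raise TopologyError(f"unknown tetrad position {p!r}")
        for g, cls in self.glycosidic.items():
            if cls not in ("syn", "anti"):
                raise TopologyError(f"unknown glycosidic class {cls!r} for {g}")

    @property
    def core_guanines(self) -> list[tuple[str, int]]:
        return [ref for tet in self.tetrads for ref in tet]

    def position_of(self, ref) -> str:
        for tet, pos in zip(self.tetrads, self.positions or ["outer"] * len(self.tetrads)):
            if ref in tet:
                return pos
        raise TopologyError(f"{ref} not in any tetrad")

    @classmethod
    def from_yaml(cls, source: str) -> "TopologySpec":
        """Load from YAML text or a file path."""
        if "\n" not in source and source.endswith((".yaml", ".yml")):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        chain = doc.get("default_chain", "A")
        tetrads = [[_parse_ref(r, chain) for r in tet]
                   for tet in doc.get("tetrads", [])]
        glyc = {}
        for key, val in (doc.get("glycosidic") or {}).items():
            glyc[_parse_ref(key, chain)] = val
        if not glyc and doc.get("all_anti", False):
            glyc = {ref: "anti" for tet in tetrads for ref in tet}
        peaks = []
        for p in doc.get("noe_peaks") or []:
            ca, na = _parse_ref(p["from"], chain), p["from_atom"]
            cb, nb = _parse_ref(p["to"], chain), p["to_atom"]
            peaks.append({
                "from": (ca[0], ca[1], na), "to": (cb[0], cb[1], nb),
                "class": p["class"],
                "exchangeable": bool(p.get("exchangeable", False)),
                "methyl": bool(p.get("methyl", False)),
            })
        return cls(tetrads=tetrads, positions=doc.get("positions", []),
                   glycosidic=glyc, noe_peaks=peaks, name=doc.get("name", ""))


@dataclass
class DistanceRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    target: float
    minus: float
    plus: float
    kind: str = "noe"        # {hbond, noe}

    def __post_init__(self):
        if self.target <= 0 or self.minus < 0 or self.plus < 0:
            raise ValueError("invalid restraint bounds")


@dataclass
class DihedralRestraint:
    atoms: tuple[AtomRef, AtomRef, AtomRef, AtomRef]
    center: float
    width: float


@dataclass
class PlanarityRestraint:
    members: list[tuple[str, int]]
    weight: float = PLANARITY_WEIGHT


@dataclass
class RestraintSet:
    hbond: list[DistanceRestraint] = field(default_factory=list)
    noe: list[DistanceRestraint] = field(default_factory=list)
    dihedral: list[DihedralRestraint] = field(default_factory=list)
    planarity: list[PlanarityRestraint] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "hbond": len(self.hbond),
            "noe": len(self.noe),
            "dihedral": len(self.dihedral),
            "planarity": len(self.planarity),
        }


# ---------------------------------------------------------------------------
# builders

def build_hbond_restraints(spec: TopologySpec) -> list[DistanceRestraint]:
    """Four Hoogsteen distance restraints per directed pair of each tetrad."""
    out = []
    for tet in spec.tetrads:
        for k in range(4):
            donor, acceptor = tet[k], tet[(k + 1) % 4]
            for da, aa, target, minus, plus in HOOGSTEEN_RESTRAINTS:
                out.append(DistanceRestraint(
                    atom_a=(donor[0], donor[1], da),
                    atom_b=(acceptor[0], acceptor[1], aa),
                    target=target, minus=minus, plus=plus, kind="hbond"))
    return out


def build_dihedral_restraints(spec: TopologySpec) -> list[DihedralRestraint]:
    """One χ restraint per anti core guanine (240 ± 70 outer / ± 40 inner)."""
    import logging
    out = []
    for tet, pos in zip(spec.tetrads,
                        spec.positions or ["outer"] * len(spec.tetrads)):
        for ref in tet:
            cls = spec.glycosidic.get(ref, "anti")
            if cls == "syn":
                logging.getLogger(__name__).warning(
                    "no χ window defined for syn guanine %s; skipped", ref)
                continue
            chain, num = ref
            out.append(DihedralRestraint(
                atoms=((chain, num, "O4'"), (chain, num, "C1'"),
                       (chain, num, "N9"), (chain, num, "C4")),
                center=CHI_CENTER, width=CHI_WIDTH[pos]))
    return out


def build_planarity_restraints(spec: TopologySpec) -> list[PlanarityRestraint]:
    """One planarity group per declared tetrad."""
    return [PlanarityRestraint(members=list(tet)) for tet in spec.tetrads]


def classify_noe(noe_class: str, exchangeable: bool = False,
                 methyl: bool = False) -> tuple[float, float, float]:
    """(target, minus, plus) for an NOE class; methyl overrides exchangeable."""
    category = ("methyl" if methyl
                else "exchangeable" if exchangeable else "non-exchangeable")
    table = NOE_CLASS_TABLE[category]
    if noe_class not in table:
        raise KeyError(
            f"NOE class {noe_class!r} undefined for category {category!r}")
    return table[noe_class]


def build_noe_restraints(spec: TopologySpec) -> list[DistanceRestraint]:
    out = []
    for p in spec.noe_peaks:
        target, minus, plus = classify_noe(p["class"], p["exchangeable"], p["methyl"])
        out.append(DistanceRestraint(atom_a=tuple(p["from"]), atom_b=tuple(p["to"]),
                                     target=target, minus=minus, plus=plus))
    return out


def build_restraints(spec: TopologySpec) -> RestraintSet:
    return RestraintSet(
        hbond=build_hbond_restraints(spec),
        noe=build_noe_restraints(spec),
        dihedral=build_dihedral_restraints(spec),
        planarity=build_planarity_restraints(spec),
    )


# ---------------------------------------------------------------------------
# validation

def _resolve(model: StructureModel, ref: AtomRef):
    chain, num, atom = ref
    for r in model.residues:
        if r.chain_id == chain and r.seq_number == num:
            return r.coord(atom)
    return None


def validate(model: StructureModel, restraints: RestraintSet,
             violation_threshold: float = 0.2) -> dict:
    """Check a coordinate model against a restraint set.

    A distance restraint is violated when the measured distance exceeds
    target+plus+threshold or falls below target−minus−threshold; a dihedral
    when the circular distance from the centre exceeds the width. Restraints
    whose atoms are missing (e.g. protons in a crystal structure) are
    counted ``unevaluable``, not violated. Planarity is reported as the RMS
    out-of-plane deviation of each group's base atoms against a 0.5 Å
    threshold.
    """
    report = {"violations": [], "unevaluable": [], "satisfied": 0,
              "planarity_rms": []}
    for r in list(restraints.hbond) + list(restraints.noe):
        pa, pb = _resolve(model, r.atom_a), _resolve(model, r.atom_b)
        if pa is None or pb is None:
            report["unevaluable"].append(("distance", r))
            continue
        d = float(np.linalg.norm(pa - pb))
        lo = r.target - r.minus - violation_threshold
        hi = r.target + r.plus + violation_threshold
        if d < lo or d > hi:
            report["violations"].append(
                ("distance", r, round(d, 3), round(max(lo - d, d - hi), 3)))
        else:
            report["satisfied"] += 1
    for r in restraints.dihedral:
        pts = [_resolve(model, a) for a in r.atoms]
        if any(p is None for p in pts):
            report["unevaluable"].append(("dihedral", r))
            continue
        ang = dihedral(*pts) % 360.0
        dev = circular_distance(ang, r.center)
        if dev > r.width:
            report["violations"].append(("dihedral", r, round(ang, 2),
                                         round(dev - r.width, 2)))
        else:
            report["satisfied"] += 1
    from ._ideal_guanine import RING_ATOMS
    for r in restraints.planarity:
        pts = []
        for chain, num in r.members:
            for res in model.residues:
                if res.chain_id == chain and res.seq_number == num:
                    pts.extend(p for p in (res.coord(n) for n in RING_ATOMS + ["O6", "N2"])
                               if p is not None)
        if len(pts) < 3:
            report["unevaluable"].append(("planarity", r))
            continue
        pts = np.array(pts)
        centre, normal = fit_plane(pts)
        rms = float(np.sqrt(np.mean(((pts - centre) @ normal) ** 2)))
        report["planarity_rms"].append((r.members, round(rms, 3),
                                        rms > PLANARITY_RMS_THRESHOLD))
    report["n_violations"] = len(report["violations"])
    report["n_unevaluable"] = len(report["unevaluable"])
    return report


# ---------------------------------------------------------------------------
# export

def _xplor_sel(ref: AtomRef) -> str:
    chain, num, atom = ref
    return f"(segid {chain} and resid {num:d} and name {atom})"


def export_restraints(restraints: RestraintSet, dialect: str = "xplor-tbl") -> str:
    """Serialize distance/dihedral restraints as XPLOR/CNS .tbl or TSV."""
    total = sum(restraints.counts.values())
    if total == 0:
        raise ValueError("cannot export an empty restraint set")
    if dialect == "xplor-tbl":
        lines = []
        for r in list(restraints.hbond) + list(restraints.noe):
            for _, _, atom in (r.atom_a, r.atom_b):
                if len(atom) > 4:
                    raise ValueError(f"atom name {atom!r} invalid for XPLOR")
            lines.append(f"assign {_xplor_sel(r.atom_a)} {_xplor_sel(r.atom_b)} "
                         f"{r.target:.2f} {r.minus:.2f} {r.plus:.2f}")
        for r in restraints.dihedral:
            sels = " ".join(_xplor_sel(a) for a in r.atoms)
            lines.append(f"assign {sels} 1.0 {r.center:.1f} {r.width:.1f} 2")
        return "\n".join(lines) + "\n"
    if dialect == "tsv":
        rows = []
        for kind, rl in (("hbond", restraints.hbond), ("noe", restraints.noe)):
            for r in rl:
                rows.append({"kind": kind,
                             "atom_a": "/".join(map(str, r.atom_a)),
                             "atom_b": "/".join(map(str, r.atom_b)),
                             "target": r.target, "minus": r.minus, "plus": r.plus})
        for r in restraints.dihedral:
            rows.append({"kind": "dihedral",
                         "atom_a": "/".join(map(str, r.atoms[0][:2])),
                         "atom_b": "/".join(map(str, r.atoms[3][:2])),
                         "target": r.center, "minus": r.width, "plus": r.width})
        for r in restraints.planarity:
            rows.append({"kind": "planarity",
                         "atom_a": ";".join(f"{c}/{n}" for c, n in r.members),
                         "atom_b": "", "target": r.weight, "minus": 0.0, "plus": 0.0})
        return pd.DataFrame(rows).to_csv(sep="\t", index=False)
    raise ValueError(f"unknown dialect {dialect!r}")


def parse_restraints_tsv(text: str) -> dict[str, int]:
    """Counts by kind from a TSV export (round-trip check)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    return df["kind"].value_counts().to_dict()
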