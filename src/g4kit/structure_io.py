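"""Atomic-coordinate I/O and selection utilities.

Reading goes through :mod:`gemmi` (PDB and mmCIF); writing emits fixed-width
PDB v3 text. The in-memory model is a small hierarchy of dataclasses —
:class:`Atom`, :class:`Residue`, :class:`StructureModel`, :class:`Ensemble` —
holding author numbering and unmodified coordinates, which every analysis
module consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom", "Residue", "StructureModel", "Ensemble",
    "read_structure", "write_structure", "select_atoms",
    "StructureParseError", "EmptyInputError", "SelectionError",
]


class StructureParseError(ValueError):
    pass


class EmptyInputError(StructureParseError):
    pass


class SelectionError(KeyError):
    pass


#: residue-name → one-letter base, for both deoxy and bare dialects
BASE_MAP = {
    "DG": "G", "DA": "A", "DT": "T", "DC": "C",
    "G": "G", "A": "A", "T": "T", "C": "C",
}

#: canonical atom-name order for deoxynucleotides (backbone 5'→3', sugar,
#: then base); unknown names sort after these, alphabetically.
_CANONICAL_ATOM_ORDER = [
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "C1'",
    "N9", "C8", "N7", "C5", "C6", "O6", "N6", "N1", "C2", "N2", "O2",
    "N3", "C4", "O4", "N4", "C7",
]
_ATOM_RANK = {n: i for i, n in enumerate(_CANONICAL_ATOM_ORDER)}

#: the guanine base-ring heavy atoms (9 purine ring atoms) plus O6
GUANINE_RING_ATOMS = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
SUGAR_ATOMS = ["C1'", "C2'", "C3'", "C4'", "O4'", "C5'"]
BACKBONE_ATOMS = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"]


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    name: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def base(self) -> str | None:
        """One-letter base, or None for non-standard residues."""
        return BASE_MAP.get(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        base = self.base or self.name
        return f"{base}{self.seq_number}"

    def get_atom(self, name: str) -> Atom | None:
        """Best altloc for ``name``: highest occupancy, ties by altloc char."""
        cands = [a for a in self.atoms if a.name == name]
        if not cands:
            return None
        return min(cands, key=lambda a: (-a.occupancy, a.altloc))

    def coord(self, name: str) -> np.ndarray | None:
        a = self.get_atom(name)
        return None if a is None else a.coords


@dataclass
class StructureModel:
    model_id: int
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in model")

    def residue(self, key) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise SelectionError(f"residue {key} not in model")

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def guanines(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer and r.base == "G"]


@dataclass
class Ensemble:
    models: list[StructureModel]

    @property
    def shared_topology(self) -> bool:
        if not self.models:
            return False
        ref = [(r.key, tuple(sorted(a.name for a in r.atoms)))
               for r in self.models[0].residues]
        return all(
            [(r.key, tuple(sorted(a.name for a in r.atoms)))
             for r in m.residues] == ref
            for m in self.models[1:]
        )


# ---------------------------------------------------------------------------
# reading

def _looks_like_path(source: str) -> bool:
    return "\n" not in source and len(source) < 4096 and os.path.exists(source)


def _guess_format(source: str, is_path: bool) -> str:
    if is_path:
        low = source.lower()
        if low.endswith((".cif", ".mmcif", ".cif.gz")):
            return "mmcif"
        return "pdb"
    head = source.lstrip()[:500]
    if head.startswith("data_") or "_atom_site" in head:
        return "mmcif"
    return "pdb"


def _from_gemmi(st: gemmi.Structure) -> Ensemble:
    st.setup_entities()
    models = []
    for i, gmodel in enumerate(st):
        residues = []
        for chain in gmodel:
            for gres in chain:
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        bfactor=a.b_iso,
                        altloc=(a.altloc if a.altloc != "\0" else ""),
                    )
                    for a in gres
                ]
                residues.append(Residue(
                    chain_id=chain.name,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    name=gres.name.strip(),
                    atoms=atoms,
                    is_polymer=gres.name.strip() in BASE_MAP,
                ))
        num = getattr(gmodel, "num", None)
        if num is None:
            try:
                num = int(getattr(gmodel, "name", i + 1))
            except (ValueError, TypeError):
                num = i + 1
        models.append(StructureModel(model_id=num, residues=residues))
    return Ensemble(models=models)


def read_structure(source: str, format: str = "auto") -> Ensemble:
    """Read a PDB or mmCIF structure from a file path or raw text.

    All models are returned; hydrogens, altlocs, waters and ions are
    retained (non-nucleotide residues are flagged ``is_polymer=False`` and
    excluded from analysis selections).
    """
    is_path = _looks_like_path(source)
    if is_path:
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    if not text.strip():
        raise EmptyInputError("empty structure input")
    fmt = format if format != "auto" else _guess_format(source, is_path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {fmt} input: {exc}") from exc
    ens = _from_gemmi(st)
    if not any(m.residues for m in ens.models):
        raise EmptyInputError("input contains no atoms")
    return ens


# ---------------------------------------------------------------------------
# writing

def _pdb_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} exceeds the PDB 4-character field")
    if len(name) == 4:
        return name
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(ensemble: Ensemble, format: str = "pdb") -> str:
    """Serialize an ensemble as PDB text (MODEL/ENDMDL for multi-model)."""
    if format != "pdb":
        raise ValueError("only PDB writing is supported")
    if not ensemble.models or not any(m.residues for m in ensemble.models):
        raise ValueError("cannot write an empty ensemble")
    multi = len(ensemble.models) > 1
    ids = [m.model_id for m in ensemble.models]
    if len(set(ids)) != len(ids):
        ids = list(range(1, len(ids) + 1))
    lines: list[str] = []
    for model_num, model in zip(ids, ensemble.models):
        if not model.residues:
            raise ValueError(f"model {model.model_id} has no residues")
        if multi:
            lines.append(f"MODEL     {model_num:4d}")
        serial = 1
        last_chain = None
        for res in model.residues:
            record = "ATOM  " if res.is_polymer else "HETATM"
            for atom in res.atoms:
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {_pdb_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' '}{res.name:>3s} {res.chain_id[:1]}"
                    f"{res.seq_number:4d}{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.bfactor:6.2f}          {atom.element:>2s}"
                )
                serial += 1
            last_chain = res.chain_id
        if last_chain is not None:
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# selection

def _atom_sort_key(res: Residue, atom: Atom):
    return (res.chain_id, res.seq_number, res.insertion_code,
            _ATOM_RANK.get(atom.name, len(_ATOM_RANK)), atom.name)


def select_atoms(
    model: StructureModel,
    selection: str,
    residues: list | None = None,
    include_n2_o6: bool = True,
) -> list[tuple[Residue, Atom]]:
    """Resolve a named atom mask to an ordered list of (residue, atom).

    Selections: ``guanine-base-ring`` (9 purine ring atoms, plus O6/N2 when
    ``include_n2_o6``), ``heavy``, ``sugar``, ``backbone``,
    ``by-residue-list`` and ``exclude-residues`` (the latter two take
    ``residues`` as keys or labels). Output order is canonical (chain,
    residue, canonical atom-name rank) regardless of file record order; one
    best-occupancy altloc per atom name.
    """
    def resolve_keys(wanted):
        keys = set()
        labels = {r.label: r.key for r in model.residues}
        missing = []
        for w in wanted or []:
            if isinstance(w, tuple):
                if w in {r.key for r in model.residues}:
                    keys.add(w)
                else:
                    missing.append(w)
            elif w in labels:
                keys.add(labels[w])
            else:
                missing.append(w)
        if missing:
            raise SelectionError(f"unknown residues in list: {missing}")
        return keys

    out: list[tuple[Residue, Atom]] = []
    if selection == "by-residue-list":
        keys = resolve_keys(residues)
        pool = [r for r in model.residues if r.key in keys]
        name_filter = None
    elif selection == "exclude-residues":
        keys = resolve_keys(residues)
        pool = [r for r in model.polymer_residues() if r.key not in keys]
        name_filter = None
    elif selection == "guanine-base-ring":
        pool = model.guanines()
        name_filter = set(GUANINE_RING_ATOMS) | ({"O6", "N2"} if include_n2_o6 else set())
    elif selection == "heavy":
        pool = model.polymer_residues()
        name_filter = None
    elif selection == "sugar":
        pool = model.polymer_residues()
        name_filter = set(SUGAR_ATOMS)
    elif selection == "backbone":
        pool = model.polymer_residues()
        name_filter = set(BACKBONE_ATOMS)
    else:
        raise SelectionError(f"unknown selection {selection!r}")

    for res in pool:
        names = sorted({a.name for a in res.atoms})
        for name in names:
            atom = res.get_atom(name)
            if atom.element == "H":
                continue
            if name_filter is not None and name not in name_filter:
                continue
            out.append((res, atom))
    out.sort(key=lambda ra: _atom_sort_key(*ra))
    return out


def coords_of(pairs: list[tuple[Residue, Atom]]) -> np.ndarray:
    """Stack the coordinates of a selection into an n×3 array."""
    return np.array([a.coords for _, a in pairs], dtype=float)
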