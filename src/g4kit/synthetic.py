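"""Idealized G-quadruplex coordinate generator with known ground truth.

Builds parallel four-stranded G4 cores — right-handed, left-handed, or a
two-block hybrid joined by a 5′-5′-type stacking interface — from a rigid
idealized guanine nucleotide template. Every structural label the analysis
stack infers (tetrad membership, step handedness, block boundaries, junction
contacts, glycosidic angles) is emitted alongside the coordinates as
:class:`GroundTruth`, so the analyzers can be validated without any
deposited data.

Geometry conventions: the global stack axis is +z; strands run 5′→3′ in the
+z direction; a positive per-layer twist is a right-handed screw. Tetrad
layers are built by solving (least squares) for the in-plane pose of the
template that closes the four Hoogsteen N2–N7 / N1–O6 contacts at 2.9 Å at
the requested N9 radius. The left-handed nucleotide orientation is obtained
by a proper 180° rotation of the assembled tetrad about an in-plane axis
(never a mirror), which simultaneously reverses the donor→acceptor cyclic
sense and the axial direction of the C5′→C3′ sugar vector — the physical
coupling between tetrad polarity and helical handedness in parallel G4s.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .geometry import dihedral, fit_plane, rotation_about_axis, unit
from .structure_io import Atom, Ensemble, Residue, StructureModel

__all__ = [
    "SyntheticG4Spec", "BlockSpec", "GroundTruth",
    "build_tetrad", "build_block", "build_hybrid", "perturb",
]

from ._ideal_guanine import RING_ATOMS as _RING
from ._ideal_guanine import TEMPLATE as _TEMPLATE_RAW
from ._ideal_guanine import full_template as _template_atoms

_BASE_SET = set(_RING) | {"O6", "N2", "H1", "H21", "H22", "H8"}

HOOGSTEEN_TARGET = 2.9          # N2–N7 and N1–O6 heavy-atom target, Å
_H_TARGET = 1.95                # soft target for H21–N7 / H1–O6, Å
DEFAULT_RADIUS = 5.64           # 5-ring centroid distance from the axis, Å
DEFAULT_RISE = 3.3              # inter-layer spacing, Å
DEFAULT_TWIST = 30.0            # |per-layer twist|, degrees
DEFAULT_GAP = 3.4               # inter-block tetrad spacing at a junction, Å
CHI_DEFAULT = 240.0             # anti glycosidic angle used throughout


class GeometryError(ValueError):
    pass


def _set_chi(atoms: dict[str, np.ndarray], chi_deg: float) -> dict[str, np.ndarray]:
    """Rotate the sugar/phosphate group about the C1'–N9 bond to set χ."""
    current = dihedral(atoms["O4'"], atoms["C1'"], atoms["N9"], atoms["C4"])
    delta = chi_deg - (current % 360.0)
    axis = atoms["N9"] - atoms["C1'"]
    R = rotation_about_axis(axis, -delta)
    pivot = atoms["N9"]
    out = dict(atoms)
    for name, xyz in atoms.items():
        if name not in _BASE_SET and name != "N9":
            out[name] = pivot + R @ (xyz - pivot)
    got = dihedral(out["O4'"], out["C1'"], out["N9"], out["C4"]) % 360.0
    if abs((got - chi_deg + 180.0) % 360.0 - 180.0) > 1e-6:
        # rotation sense was the other way round
        R = rotation_about_axis(axis, delta)
        out = dict(atoms)
        for name, xyz in atoms.items():
            if name not in _BASE_SET and name != "N9":
                out[name] = pivot + R @ (xyz - pivot)
    return out


def _canonical_nucleotide(chi_deg: float = CHI_DEFAULT) -> dict[str, np.ndarray]:
    """Template in a canonical frame: base ring in the z=0 plane.

    The frame's +z side is the base face for which the cross product
    (C8−N9)×(C4−N9) points towards +z.
    """
    atoms = _set_chi(_template_atoms(), chi_deg)
    ring = np.array([atoms[n] for n in _RING])
    centroid, normal = fit_plane(ring)
    ref = np.cross(atoms["C8"] - atoms["N9"], atoms["C4"] - atoms["N9"])
    if np.dot(normal, ref) < 0:
        normal = -normal
    z = unit(normal)
    x = unit(atoms["N9"] - centroid - np.dot(atoms["N9"] - centroid, z) * z)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    return {n: R @ (p - centroid) for n, p in atoms.items()}


def _rz(angle_deg: float) -> np.ndarray:
    return rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg)


#: rotation step (degrees) taking a donor to its Hoogsteen acceptor copy;
#: the −90° sense is the one for which the amino/imino protons point at
#: their N7/O6 acceptors with near-linear hydrogen bonds.
_HOOGSTEEN_STEP = -90.0

#: the N9-containing 5-ring, whose centroid defines the tetrad radius
_RING5 = ["N9", "C8", "N7", "C5", "C4"]


def _inplane_closure(chi_deg: float, d_target: float = HOOGSTEEN_TARGET) -> np.ndarray:
    """Exact in-plane translation closing both heavy Hoogsteen contacts.

    With C4 symmetry the two heavy-atom distances determine the tetrad up to
    a global rotation: the translation satisfies two circle equations in the
    plane (intersection chosen on the branch with near-linear N–H···X
    geometry).
    """
    tmpl = _canonical_nucleotide(chi_deg)
    R90 = _rz(_HOOGSTEEN_STEP)
    c1 = tmpl["N2"] - R90 @ tmpl["N7"]
    c2 = tmpl["N1"] - R90 @ tmpl["O6"]
    r1 = np.sqrt(d_target ** 2 - c1[2] ** 2)
    r2 = np.sqrt(d_target ** 2 - c2[2] ** 2)
    p1, p2 = -c1[:2], -c2[:2]
    d = np.linalg.norm(p2 - p1)
    if d > r1 + r2 or d < abs(r1 - r2):
        raise GeometryError("Hoogsteen circles do not intersect")
    a = (r1 ** 2 - r2 ** 2 + d ** 2) / (2 * d)
    h = np.sqrt(max(r1 ** 2 - a ** 2, 0.0))
    e = (p2 - p1) / d
    eperp = np.array([-e[1], e[0]])
    w = p1 + a * e - h * eperp
    M = np.eye(2) - R90[:2, :2]
    t2 = np.linalg.solve(M, w)
    return np.array([t2[0], t2[1], 0.0])


@functools.lru_cache(maxsize=32)
def _solve_tetrad_pose(radius: float, chi_deg: float) -> tuple[tuple, tuple]:
    """Rigid pose (R, t) of copy 0 closing the Hoogsteen cycle at ``radius``.

    ``radius`` is the distance of the guanine 5-ring centroid from the stack
    axis. The exact planar closure fixes a natural radius (≈5.6 Å for the
    2.9 Å heavy-atom targets); other radii are reached by letting the base
    tilt slightly out of the tetrad plane while keeping the heavy-atom
    contacts within 2.9 ± 0.2 Å.
    """
    if not (4.0 <= radius <= 6.0):
        raise GeometryError(
            f"tetrad radius {radius} Å outside the closable range [4.0, 6.0]")
    tmpl = _canonical_nucleotide(chi_deg)
    t0 = _inplane_closure(chi_deg)
    ring5 = np.array([tmpl[n] for n in _RING5])
    natural = float(np.linalg.norm((ring5 + t0).mean(axis=0)[:2]))
    if abs(natural - radius) < 1e-6:
        return (tuple(map(tuple, np.eye(3))), tuple(t0))

    R90 = _rz(_HOOGSTEEN_STEP)
    names = ["N2", "N1", "H21", "H1", "N7", "O6"]

    def pose(params):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return R, params[3:]

    def residuals(params):
        R, t = pose(params)
        p = {n: R @ tmpl[n] + t for n in names}
        a = {n: R90 @ p[n] for n in ("N7", "O6")}
        r5 = (np.array([R @ q for q in ring5]) + t).mean(axis=0)
        ringz = np.mean([(R @ tmpl[n] + t)[2] for n in _RING])
        return [
            5.0 * (np.linalg.norm(p["N2"] - a["N7"]) - HOOGSTEEN_TARGET),
            5.0 * (np.linalg.norm(p["N1"] - a["O6"]) - HOOGSTEEN_TARGET),
            np.linalg.norm(p["H21"] - a["N7"]) - _H_TARGET,
            np.linalg.norm(p["H1"] - a["O6"]) - _H_TARGET,
            3.0 * (np.linalg.norm(r5[:2]) - radius),
            2.0 * ringz,
        ]

    sol = least_squares(residuals, x0=[0.0, 0.0, 0.0, *t0], xtol=1e-14, ftol=1e-14)
    R, t = pose(sol.x)
    p = {n: R @ tmpl[n] + t for n in ("N2", "N1")}
    a = {n: R90 @ (R @ tmpl[n] + t) for n in ("N7", "O6")}
    for dd in (np.linalg.norm(p["N2"] - a["N7"]), np.linalg.norm(p["N1"] - a["O6"])):
        if abs(dd - HOOGSTEEN_TARGET) > 0.2:
            raise GeometryError(
                f"radius {radius} Å not closable with Hoogsteen contacts "
                f"within {HOOGSTEEN_TARGET} ± 0.2 Å")
    return (tuple(map(tuple, R)), tuple(t))


def _tetrad_coords(radius: float, chi_deg: float) -> list[dict[str, np.ndarray]]:
    """Four nucleotide copies closing a planar tetrad around +z at z=0.

    Copy k donates its N1/N2 face to copy k+1 (indices mod 4); the list
    order 0→1→2→3 is the donor→acceptor cycle order.
    """
    Rtup, ttup = _solve_tetrad_pose(radius, chi_deg)
    R, t = np.array(Rtup), np.array(ttup)
    tmpl = _canonical_nucleotide(chi_deg)
    base = {n: R @ p + t for n, p in tmpl.items()}
    return [{n: _rz(_HOOGSTEEN_STEP * k) @ p for n, p in base.items()}
            for k in range(4)]


def _flip_x(coords: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Proper 180° rotation about the x-axis (y→−y, z→−z). Not a mirror."""
    F = np.diag([1.0, -1.0, -1.0])
    return {n: F @ p for n, p in coords.items()}


def sugar_axial_sign(radius: float = DEFAULT_RADIUS, chi_deg: float = CHI_DEFAULT) -> float:
    """Sign of the z-component of C5′→C3′ for the un-flipped tetrad."""
    g = _tetrad_coords(radius, chi_deg)[0]
    return float(np.sign((g["C3'"] - g["C5'"])[2]))


def _oriented_tetrad(handed: str, radius: float, chi_deg: float) -> list[dict[str, np.ndarray]]:
    """Tetrad orientation whose sugar C5′→C3′ axial sense matches ``handed``
    for a strand progressing 5′→3′ along +z (right: positive, left: negative).
    """
    guanines = _tetrad_coords(radius, chi_deg)
    want = +1.0 if handed == "right" else -1.0
    if sugar_axial_sign(radius, chi_deg) != want:
        guanines = [_flip_x(g) for g in guanines]
    return guanines


# ---------------------------------------------------------------------------
# public builders

@dataclass
class BlockSpec:
    n_layers: int = 2
    handedness: str = "right"           # {right, left}
    twist: float | None = None          # degrees/layer, signed; default ±30
    rise: float = DEFAULT_RISE          # Å

    def __post_init__(self):
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        if self.n_layers < 1:
            raise ValueError("n_layers must be ≥ 1")
        if not (2.5 <= self.rise <= 4.5):
            raise ValueError("rise must lie in [2.5, 4.5] Å")
        if self.twist is None:
            self.twist = DEFAULT_TWIST if self.handedness == "right" else -DEFAULT_TWIST
        if self.twist != 0 and (self.twist > 0) != (self.handedness == "right"):
            raise ValueError("twist sign inconsistent with handedness label")


@dataclass
class SyntheticG4Spec:
    blocks: list[BlockSpec] = field(default_factory=lambda: [BlockSpec()])
    radius: float = DEFAULT_RADIUS
    junction_mode: str = "none"         # {none, five-prime-five-prime}
    gap: float = DEFAULT_GAP
    jitter_sd: float = 0.0
    seed: int = 0
    chi: float = CHI_DEFAULT

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be ≥ 0")
        if self.junction_mode not in ("none", "five-prime-five-prime"):
            raise ValueError(f"unknown junction mode {self.junction_mode!r}")
        if self.junction_mode == "five-prime-five-prime" and len(self.blocks) != 2:
            raise ValueError("a junction requires exactly 2 blocks")


@dataclass
class GroundTruth:
    """Construction-time labels for a generated model."""
    layers: list[list[tuple[str, int, str]]] = field(default_factory=list)
    step_handedness: dict = field(default_factory=dict)
    block_layers: list[list[int]] = field(default_factory=list)
    block_handedness: list[str] = field(default_factory=list)
    junction_pairs: list[tuple] = field(default_factory=list)
    junction_polarity_relation: str | None = None
    chi: dict = field(default_factory=dict)
    rise: float = DEFAULT_RISE

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError
        doc = {
            "layers": [[list(k) for k in layer] for layer in self.layers],
            "step_handedness": {f"{k[0]}:{k[1]}->{k[2]}": v
                                for k, v in self.step_handedness.items()},
            "block_layers": self.block_layers,
            "block_handedness": self.block_handedness,
            "junction_pairs": [[list(a), list(b)] for a, b in self.junction_pairs],
            "junction_polarity_relation": self.junction_polarity_relation,
            "chi": {f"{k[0]}:{k[1]}": v for k, v in self.chi.items()},
            "rise": self.rise,
        }
        return json.dumps(doc, indent=1, default=conv)


def _residue_from_coords(coords: dict[str, np.ndarray], chain: str, seq: int) -> Residue:
    atoms = [Atom(name=n, element=_TEMPLATE_RAW[n][0], coords=coords[n].copy())
             for n in _TEMPLATE_RAW]
    return Residue(chain_id=chain, seq_number=seq, name="DG", atoms=atoms)


def _unflipped_polarity() -> str:
    """Polarity (per tetrad_core's convention) of the un-flipped tetrad."""
    from .tetrad_core import cycle_polarity
    guanines = _tetrad_coords(DEFAULT_RADIUS, CHI_DEFAULT)
    centroids = [np.mean([g[n] for n in _RING + ["O6"]], axis=0) for g in guanines]
    return cycle_polarity(np.array(centroids), np.array([0.0, 0.0, 1.0]))


def build_tetrad(polarity: str = "clockwise", radius: float = DEFAULT_RADIUS,
                 z: float = 0.0, phase: float = 0.0,
                 chi_deg: float = CHI_DEFAULT) -> list[Residue]:
    """One planar tetrad of four guanine residues around +z.

    ``polarity`` is the requested donor→acceptor cyclic sense for a viewer
    looking along +z (the convention of :func:`g4kit.tetrad_core.tetrad_polarity`).
    Residues are chains A–D, residue number 1, in donor→acceptor cycle order.
    """
    guanines = _tetrad_coords(radius, chi_deg)
    if polarity not in ("clockwise", "anticlockwise"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if polarity != _unflipped_polarity():
        guanines = [_flip_x(g) for g in guanines]
    shift = np.array([0.0, 0.0, z])
    Rp = _rz(phase)
    out = []
    for k, g in enumerate(guanines):
        coords = {n: Rp @ p + shift for n, p in g.items()}
        out.append(_residue_from_coords(coords, "ABCD"[k], 1))
    return out


def _block_residues(spec: BlockSpec, radius: float, chi_deg: float,
                    chains: str, seq_start: int, z0: float,
                    phase0: float) -> tuple[list[Residue], dict]:
    guanines = _oriented_tetrad(spec.handedness, radius, chi_deg)
    layers: list[list[Residue]] = []
    for l in range(spec.n_layers):
        Rp = _rz(phase0 + l * spec.twist)
        shift = np.array([0.0, 0.0, z0 + l * spec.rise])
        layer = []
        for k, g in enumerate(guanines):
            coords = {n: Rp @ p + shift for n, p in g.items()}
            layer.append(_residue_from_coords(coords, chains[k], seq_start + l))
        layers.append(layer)
    return layers, {"handedness": spec.handedness}


def _assemble(layer_groups: list[list[list[Residue]]]) -> StructureModel:
    residues: list[Residue] = []
    for layers in layer_groups:
        by_chain: dict[str, list[Residue]] = {}
        for layer in layers:
            for res in layer:
                by_chain.setdefault(res.chain_id, []).append(res)
        for chain in sorted(by_chain):
            residues.extend(sorted(by_chain[chain], key=lambda r: r.seq_number))
    residues.sort(key=lambda r: (r.chain_id, r.seq_number))
    return StructureModel(model_id=1, residues=residues)


def build_block(spec: BlockSpec, radius: float = DEFAULT_RADIUS,
                chi_deg: float = CHI_DEFAULT) -> tuple[StructureModel, GroundTruth]:
    """A single parallel G4 block: 4 strands (chains A–D), ``n_layers`` layers.

    Strand 5′→3′ runs bottom (layer 0) to top; residue numbers follow layers.
    """
    layers, _ = _block_residues(spec, radius, chi_deg, "ABCD", 1, 0.0, 0.0)
    model = _assemble([layers])
    truth = GroundTruth(rise=spec.rise)
    truth.layers = [[r.key for r in layer] for layer in layers]
    truth.block_layers = [list(range(spec.n_layers))]
    truth.block_handedness = [spec.handedness]
    for l in range(spec.n_layers - 1):
        for k in range(4):
            r5, r3 = layers[l][k], layers[l + 1][k]
            truth.step_handedness[(r5.chain_id, r5.seq_number, r3.seq_number)] = spec.handedness
    for layer in layers:
        for r in layer:
            truth.chi[(r.chain_id, r.seq_number)] = chi_deg
    return model, truth


def _greedy_c1_pairs(top_layer: list[Residue], bottom_layer: list[Residue]):
    """Greedy nearest-neighbour C1′–C1′ pairing, each residue used once."""
    cands = []
    for a in top_layer:
        for b in bottom_layer:
            d = float(np.linalg.norm(a.coord("C1'") - b.coord("C1'")))
            cands.append((d, a, b))
    cands.sort(key=lambda x: x[0])
    used_a, used_b, pairs = set(), set(), []
    for d, a, b in cands:
        if a.key in used_a or b.key in used_b:
            continue
        used_a.add(a.key)
        used_b.add(b.key)
        pairs.append((a, b, d))
    return pairs


def build_hybrid(spec: SyntheticG4Spec) -> tuple[StructureModel, GroundTruth]:
    """Two coaxial blocks stacked with a 5′-5′-type sugar interface.

    The lower block is placed first (layers 0..n−1 from the bottom); the
    upper block continues upward separated by ``spec.gap``. Both blocks'
    strands run 5′→3′ along +z, so for a right-on-top-of-left arrangement
    the two interface tetrads carry opposite cyclic polarity by construction.
    The upper block's azimuth is chosen (deterministic scan) to minimize the
    worst of the four interface C1′–C1′ contacts.
    """
    if spec.junction_mode != "five-prime-five-prime":
        raise ValueError("build_hybrid requires junction_mode='five-prime-five-prime'")
    lower, upper = spec.blocks
    low_layers, _ = _block_residues(lower, spec.radius, spec.chi, "ABCD", 1, 0.0, 0.0)
    z_top = (lower.n_layers - 1) * lower.rise + spec.gap

    def interface_quality(phase0):
        up_layer, _ = _block_residues(
            BlockSpec(1, upper.handedness, None, upper.rise),
            spec.radius, spec.chi, "EFGH", 101, z_top, phase0)
        pairs = _greedy_c1_pairs(up_layer[0], low_layers[-1])
        return max(d for _, _, d in pairs)

    phases = np.arange(0.0, 360.0, 2.0)
    best_phase = min(phases, key=interface_quality)
    up_layers, _ = _block_residues(upper, spec.radius, spec.chi, "EFGH", 101,
                                   z_top, float(best_phase))
    model = _assemble([low_layers, up_layers])

    truth = GroundTruth(rise=lower.rise)
    all_layers = low_layers + up_layers
    truth.layers = [[r.key for r in layer] for layer in all_layers]
    nL = lower.n_layers
    truth.block_layers = [list(range(nL)), list(range(nL, nL + upper.n_layers))]
    truth.block_handedness = [lower.handedness, upper.handedness]
    for layers, spec_b in ((low_layers, lower), (up_layers, upper)):
        for l in range(len(layers) - 1):
            for k in range(4):
                r5, r3 = layers[l][k], layers[l + 1][k]
                truth.step_handedness[(r5.chain_id, r5.seq_number, r3.seq_number)] = spec_b.handedness
    pairs = _greedy_c1_pairs(up_layers[0], low_layers[-1])
    truth.junction_pairs = [(a.key, b.key) for a, b, _ in pairs]
    truth.junction_polarity_relation = (
        "opposite" if lower.handedness != upper.handedness else "same")
    for layer in all_layers:
        for r in layer:
            truth.chi[(r.chain_id, r.seq_number)] = spec.chi
    return model, truth


def build(spec: SyntheticG4Spec) -> tuple[StructureModel, GroundTruth]:
    """Build the model a spec describes (single block or hybrid), jittered."""
    if spec.junction_mode == "five-prime-five-prime":
        model, truth = build_hybrid(spec)
    elif len(spec.blocks) == 1:
        model, truth = build_block(spec.blocks[0], spec.radius, spec.chi)
    else:
        raise ValueError("multiple blocks require a junction mode")
    if spec.jitter_sd > 0:
        model = perturb(model, spec.jitter_sd, spec.seed)
    return model, truth


def perturb(model: StructureModel, jitter_sd: float, seed: int = 0) -> StructureModel:
    """Isotropic per-atom Gaussian jitter (sd per coordinate component)."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    residues = []
    for res in model.residues:
        atoms = []
        for a in res.atoms:
            shift = rng.normal(0.0, jitter_sd, 3) if jitter_sd > 0 else 0.0
            atoms.append(Atom(a.name, a.element, a.coords + shift,
                              a.occupancy, a.bfactor, a.altloc))
        residues.append(Residue(res.chain_id, res.seq_number, res.insertion_code,
                                res.name, atoms, res.is_polymer))
    return StructureModel(model_id=model.model_id, residues=residues)


def as_ensemble(model: StructureModel) -> Ensemble:
    return Ensemble(models=[model])
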