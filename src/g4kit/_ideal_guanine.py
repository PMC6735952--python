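"""Idealized 2'-deoxyguanosine coordinates.

Heavy atoms plus the protons the analyses use (imino H1, amino H21/H22,
aromatic H8, anomeric H1'), taken from the wwPDB chemical component
dictionary ideal coordinate set for DG. The base subset serves as the
standard reference frame for rigid base fitting (the 3DNA/DSSR convention);
the full nucleotide is the synthetic generator's building template.
"""

from __future__ import annotations

import numpy as np

#: name → (element, ideal xyz in Å)
TEMPLATE = {
    "P":   ("P", (-0.818, -0.321, 4.935)),
    "OP1": ("O", (-1.774, 0.766, 4.630)),
    "OP2": ("O", (0.312, 0.224, 5.941)),
    "O5'": ("O", (-0.126, -0.826, 3.572)),
    "C5'": ("C", (0.550, 0.300, 3.011)),
    "C4'": ("C", (1.233, -0.113, 1.706)),
    "O4'": ("O", (0.253, -0.471, 0.705)),
    "C3'": ("C", (1.976, 1.091, 1.073)),
    "O3'": ("O", (3.294, 1.218, 1.612)),
    "C2'": ("C", (2.026, 0.692, -0.421)),
    "C1'": ("C", (0.897, -0.345, -0.573)),
    "N9":  ("N", (-0.068, 0.111, -1.575)),
    "C8":  ("C", (-1.172, 0.877, -1.341)),
    "N7":  ("N", (-1.804, 1.094, -2.458)),
    "C5":  ("C", (-1.145, 0.482, -3.472)),
    "C6":  ("C", (-1.361, 0.377, -4.866)),
    "O6":  ("O", (-2.321, 0.914, -5.391)),
    "N1":  ("N", (-0.473, -0.327, -5.601)),
    "C2":  ("C", (0.593, -0.928, -5.003)),
    "N2":  ("N", (1.474, -1.643, -5.774)),
    "N3":  ("N", (0.804, -0.839, -3.709)),
    "C4":  ("C", (-0.027, -0.152, -2.917)),
    "H1":  ("H", (-0.601, -0.413, -6.559)),
    # Amino proton labels follow the G4 NMR naming (as in XPLOR topology
    # files): H21 is the proton syn to N1 — the one donated to N7 in a
    # Hoogsteen G•G pair.
    "H21": ("H", (1.329, -1.722, -6.730)),
    "H22": ("H", (2.240, -2.073, -5.363)),
    "H8":  ("H", (-1.477, 1.248, -0.373)),
    "H1'": ("H", (1.316, -1.306, -0.873)),
}

#: the nine purine ring heavy atoms
RING_ATOMS = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]

#: heavy atoms used for rigid base-frame fitting: the base plus C1', whose
#: position relative to the base is glycosidic-torsion invariant
BASE_FRAME_ATOMS = RING_ATOMS + ["O6", "N2", "C1'"]


def base_frame_reference() -> dict[str, np.ndarray]:
    """Ideal base heavy-atom coordinates for frame fitting."""
    return {n: np.array(TEMPLATE[n][1], dtype=float) for n in BASE_FRAME_ATOMS}


def full_template() -> dict[str, np.ndarray]:
    return {n: np.array(v[1], dtype=float) for n, v in TEMPLATE.items()}


def element_of(name: str) -> str:
    return TEMPLATE[name][0]
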