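"""Idealized nucleobase geometry in a common base-pair reference frame.

Each of the four deoxyribonucleotide bases is stored as heavy-atom
coordinates (plus the glycosidic C1' attachment point) in the standard
base-pair reference frame: the helix axis of an ideal B-form duplex
runs along +z through the origin, and the Watson-Crick partner of a
base is obtained by a 180 degree rotation about the x axis.  Because
all four bases share one frame, replacing a base by any other while
keeping the frame fixed performs an in-place base-pair substitution.

The glycosidic frame used to anchor a base to an existing nucleotide
consists of C1', the glycosidic nitrogen (N9 for purines, N1 for
pyrimidines) and one ring anchor (C4 purines / C2 pyrimidines).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BASES",
    "COMPLEMENT",
    "BASE_COORDS",
    "base_atoms",
    "frame_atom_names",
    "glycosidic_frame",
    "frame_transform",
]

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# residue code for a base letter
RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
BASE_OF_RESNAME = {v: k for k, v in RESNAME.items()}

# Heavy-atom coordinates (A) in the standard base-pair reference frame.
_A = {
    "C1'": (-2.479, 5.346, 0.000),
    "N9": (-1.291, 4.498, 0.000),
    "C8": (0.024, 4.897, 0.000),
    "N7": (0.877, 3.902, 0.000),
    "C5": (0.071, 2.771, 0.000),
    "C6": (0.369, 1.398, 0.000),
    "N6": (1.611, 0.909, 0.000),
    "N1": (-0.668, 0.532, 0.000),
    "C2": (-1.912, 1.023, 0.000),
    "N3": (-2.320, 2.290, 0.000),
    "C4": (-1.267, 3.124, 0.000),
}
_G = {
    "C1'": (-2.477, 5.399, 0.000),
    "N9": (-1.289, 4.551, 0.000),
    "C8": (0.023, 4.962, 0.000),
    "N7": (0.870, 3.969, 0.000),
    "C5": (0.071, 2.833, 0.000),
    "C6": (0.424, 1.460, 0.000),
    "O6": (1.554, 0.955, 0.000),
    "N1": (-0.700, 0.641, 0.000),
    "C2": (-1.999, 1.087, 0.000),
    "N2": (-2.949, 0.139, 0.000),
    "N3": (-2.342, 2.364, 0.000),
    "C4": (-1.265, 3.177, 0.000),
}
_C = {
    "C1'": (-2.477, 5.402, 0.000),
    "N1": (-1.285, 4.542, 0.000),
    "C2": (-1.472, 3.158, 0.000),
    "O2": (-2.628, 2.709, 0.000),
    "N3": (-0.391, 2.344, 0.000),
    "C4": (0.837, 2.868, 0.000),
    "N4": (1.875, 2.027, 0.000),
    "C5": (1.056, 4.275, 0.000),
    "C6": (-0.023, 5.068, 0.000),
}
_T = {
    "C1'": (-2.481, 5.354, 0.000),
    "N1": (-1.284, 4.500, 0.000),
    "C2": (-1.462, 3.135, 0.000),
    "O2": (-2.562, 2.608, 0.000),
    "N3": (-0.298, 2.407, 0.000),
    "C4": (0.994, 2.897, 0.000),
    "O4": (1.944, 2.119, 0.000),
    "C5": (1.106, 4.338, 0.000),
    "C7": (2.466, 4.961, 0.000),
    "C6": (-0.024, 5.057, 0.000),
}

BASE_COORDS: dict[str, dict[str, np.ndarray]] = {
    b: {name: np.array(xyz, dtype=float) for name, xyz in d.items()}
    for b, d in (("A", _A), ("G", _G), ("C", _C), ("T", _T))
}

# One shared glycosidic attachment point for all four bases (the mean of
# the per-base values, which differ by < 0.06 A).  Sharing it makes base
# replacement closed under composition: any chain of substitutions at a
# position reproduces the exact same placement transform, so threading
# results cannot depend on which sequence happened to sit in the template.
_CANONICAL_C1P = np.array([-2.4785, 5.3753, 0.0])
for _b in BASES:
    BASE_COORDS[_b]["C1'"] = _CANONICAL_C1P.copy()

_PURINES = ("A", "G")


def frame_atom_names(base: str) -> tuple[str, str, str]:
    """(C1', glycosidic N, ring anchor) atom names for a base letter."""
    if base in _PURINES:
        return ("C1'", "N9", "C4")
    return ("C1'", "N1", "C2")


def base_atoms(base: str) -> list[tuple[str, np.ndarray]]:
    """Base-moiety atoms (excluding C1') in library order."""
    return [(n, xyz.copy()) for n, xyz in BASE_COORDS[base].items() if n != "C1'"]


def glycosidic_frame(c1p: np.ndarray, n_gly: np.ndarray, anchor: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame (origin, 3x3 basis) anchored at C1'.

    e1 points from C1' to the glycosidic nitrogen, e2 lies in the
    C1'/N/anchor plane, e3 completes the right-handed basis.  The
    construction is equivariant under rigid motions, which makes base
    placement a pure function of the three frame atoms.
    """
    e1 = n_gly - c1p
    norm1 = np.linalg.norm(e1)
    if norm1 < 1e-6:
        raise ValueError("degenerate glycosidic frame (C1' == N)")
    e1 = e1 / norm1
    v = anchor - c1p
    e2 = v - np.dot(v, e1) * e1
    norm2 = np.linalg.norm(e2)
    if norm2 < 1e-6:
        raise ValueError("degenerate glycosidic frame (collinear atoms)")
    e2 = e2 / norm2
    e3 = np.cross(e1, e2)
    return c1p, np.column_stack([e1, e2, e3])


def frame_transform(base: str, c1p: np.ndarray, n_gly: np.ndarray,
                    anchor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid map (R, t) taking library coordinates of ``base`` onto a
    nucleotide whose observed frame atoms are given.

    The map carries the library C1' exactly onto the observed C1'.
    Apply as ``x @ R.T + t``.
    """
    names = frame_atom_names(base)
    lib = BASE_COORDS[base]
    lo, lb = glycosidic_frame(lib[names[0]], lib[names[1]], lib[names[2]])
    oo, ob = glycosidic_frame(c1p, n_gly, anchor)
    R = ob @ lb.T
    t = oo - R @ lo
    return R, t
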