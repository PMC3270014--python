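"""Synthetic structures: idealized B-DNA, toy complexes, planted corpora.

Everything downstream of structure parsing is testable without any
database download: this module generates

* idealized B-form DNA duplexes (uniform rise 3.38 A, twist 36
  degrees per step, base geometry from the shared base library),
* toy protein-DNA complexes -- a stylized poly-alanine chain arcs
  around the duplex at a non-interacting radius, and designated atoms
  are relocated to planted distances from designated DNA atoms,
* corpora of such complexes in which a fixed protein atom type is
  repeatedly planted 3-4 A from the discriminating base atom of one
  preferred base and kept >=8 A away from the discriminating atoms of
  the other bases, which lets an end-to-end run recover the planted
  preference.

The geometry is deliberately idealized (rigid library bases, uniform
helical parameters, stylized sugar-phosphate backbone and protein
chain); it exercises contact counting and threading, not stereochemistry.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import baselib
from .baselib import BASES, COMPLEMENT, RESNAME
from .structio import Atom, Complex

__all__ = [
    "FixtureSpec",
    "DISCRIMINATING_ATOM",
    "make_bdna",
    "make_protein_arc",
    "make_toy_complex",
    "make_planted_kb_corpus",
    "PlantingError",
]

RISE = 3.38       # A per base-pair step
TWIST = 36.0      # degrees per step
PROTEIN_RADIUS = 23.0   # arc radius; >10 A from every duplex atom (r <= 11.3)

# major-groove atom unique to each base, used for planted preferences
DISCRIMINATING_ATOM = {"A": "N6", "G": "O6", "C": "N4", "T": "O4"}

_SUGAR_RING = ("C1'", "C2'", "C3'", "C4'", "O4'")


class PlantingError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy protein-DNA complex.

    planted_contacts: tuples (protein atom type "RES.NAME", DNA atom
    type "RES.NAME", distance in A, duplex position on the reference
    strand).  The designated protein atoms are relocated to the given
    distances radially outward from the designated DNA atoms.
    """

    dna_sequence: str
    protein_size: int = 45
    planted_contacts: tuple = ()
    seed: int = 0
    resolution: float = 2.0
    method: str = "X-RAY DIFFRACTION"
    name: str = "toy"


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

_FLIP_X = np.diag([1.0, -1.0, -1.0])  # Watson-Crick partner placement


def _backbone_template(c1p: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Stylized deoxyribose + phosphate attached at a given C1'.

    Built in the standard base-pair frame (helix axis = z); the sugar
    ring is a regular pentagon through C1', the 3' oxygen points
    towards the next residue (+z for the reference strand) and the
    phosphate towards the previous one.
    """
    z = np.array([0.0, 0.0, 1.0])
    radial = np.array([c1p[0], c1p[1], 0.0])
    u = radial / np.linalg.norm(radial)          # outward
    t = np.cross(z, u)                            # tangential

    ring_r = 1.29                                 # pentagon circumradius
    e1 = 0.80 * u - 0.20 * t - 0.55 * z
    e1 /= np.linalg.norm(e1)
    center = c1p + ring_r * e1
    a = -e1
    b = np.cross(e1, z)
    b /= np.linalg.norm(b)
    ring = {}
    for k, name in enumerate(_SUGAR_RING):
        ang = np.deg2rad(72.0 * k)
        ring[name] = center + ring_r * (np.cos(ang) * a + np.sin(ang) * b)

    def stretch(origin, direction, length):
        d = np.asarray(direction, dtype=float)
        return origin + length * d / np.linalg.norm(d)

    out_c3 = ring["C3'"] - center
    out_c4 = ring["C4'"] - center
    o3p = stretch(ring["C3'"], 0.6 * out_c3 + 0.9 * z, 1.42)
    c5p = stretch(ring["C4'"], 0.5 * out_c4 - 1.0 * z, 1.51)
    o5p = stretch(c5p, 0.4 * u - 0.9 * z + 0.2 * t, 1.43)
    p = stretch(o5p, 0.5 * u - 0.75 * z - 0.4 * t, 1.60)
    op1 = stretch(p, 0.3 * u + 0.9 * t - 0.3 * z, 1.48)
    op2 = stretch(p, 0.9 * u - 0.4 * t + 0.2 * z, 1.48)

    ordered = [("P", p), ("OP1", op1), ("OP2", op2), ("O5'", o5p),
               ("C5'", c5p), ("C4'", ring["C4'"]), ("O4'", ring["O4'"]),
               ("C3'", ring["C3'"]), ("O3'", o3p), ("C2'", ring["C2'"])]
    return [(n, xyz.copy()) for n, xyz in ordered]


def _nucleotide_template(base: str) -> list[tuple[str, np.ndarray]]:
    """Full heavy-atom nucleotide (backbone + base) in the standard frame."""
    c1p = baselib.BASE_COORDS[base]["C1'"]
    atoms = _backbone_template(c1p)
    atoms.append(("C1'", c1p.copy()))
    atoms.extend(baselib.base_atoms(base))
    return atoms


def make_bdna(sequence: str, chain1: str = "B", chain2: str = "C",
              name: str = "bdna") -> Complex:
    """Idealized B-form duplex for a 5'->3' reference-strand sequence.

    Both strands carry full heavy-atom nucleotides with standard PDB
    names; 5'-terminal residues have no phosphate group.  Every
    position is Watson-Crick paired by construction.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    if any(b not in BASES for b in sequence):
        raise ValueError("sequence alphabet must be ACGT")

    atoms: list[Atom] = []

    def emit(chain_id, resnum, base, R, shift, drop_phosphate):
        resname = RESNAME[base]
        for atom_name, xyz in _nucleotide_template(base):
            if drop_phosphate and atom_name in ("P", "OP1", "OP2"):
                continue
            atoms.append(Atom(
                chain_id=chain_id,
                residue_name=resname,
                residue_number=resnum,
                atom_name=atom_name,
                element=atom_name[0],
                coords=R @ xyz + shift,
            ))

    n = len(sequence)
    for i, base in enumerate(sequence):
        R = _rot_z(i * TWIST)
        shift = np.array([0.0, 0.0, i * RISE])
        emit(chain1, i + 1, base, R, shift, drop_phosphate=(i == 0))
    # partner strand, 5'->3' (opposite helical direction)
    for k in range(n):
        i = n - 1 - k                      # paired reference position
        base = COMPLEMENT[sequence[i]]
        R = _rot_z(i * TWIST) @ _FLIP_X
        shift = np.array([0.0, 0.0, i * RISE])
        emit(chain2, k + 1, base, R, shift, drop_phosphate=(k == 0))

    return Complex(atoms, name=name)


def make_protein_arc(n_residues: int, chain_id: str = "A",
                     z_center: float = 0.0, phase: float = 0.0
                     ) -> list[Atom]:
    """Stylized poly-alanine chain arcing around the helix axis.

    All atoms sit at radius ~23 A, more than 10 A from any duplex
    atom, so only deliberately planted atoms produce contacts.
    """
    atoms: list[Atom] = []
    dz = 1.2
    dphi = 2.0 * np.arcsin(np.sqrt(3.8 ** 2 - dz ** 2) / (2 * PROTEIN_RADIUS))
    for j in range(n_residues):
        phi = phase + j * dphi
        zc = z_center + (j - n_residues / 2) * dz
        ca = np.array([PROTEIN_RADIUS * np.cos(phi),
                       PROTEIN_RADIUS * np.sin(phi), zc])
        u = np.array([np.cos(phi), np.sin(phi), 0.0])      # outward
        t = np.array([-np.sin(phi), np.cos(phi), 0.0])     # chain direction
        z = np.array([0.0, 0.0, 1.0])
        local = {
            "N": ca - 1.20 * t,
            "CA": ca,
            "C": ca + 1.20 * t,
            "O": ca + 1.20 * t + 1.23 * (0.5 * u + 0.866 * z),
            "CB": ca + 1.53 * u,
        }
        for atom_name in ("N", "CA", "C", "O", "CB"):
            atoms.append(Atom(
                chain_id=chain_id,
                residue_name="ALA",
                residue_number=j + 1,
                atom_name=atom_name,
                element=atom_name[0],
                coords=local[atom_name],
            ))
    return atoms


def make_toy_complex(spec: FixtureSpec) -> Complex:
    """B-DNA plus a synthetic protein chain with planted contacts.

    Deterministic under ``spec.seed`` (the seed sets the arc phase and
    axial placement of the protein chain).  Raises
    :class:`PlantingError` if a planted atom would clash (< 1.5 A)
    with any other atom or if the requested DNA atom does not exist at
    the requested position.
    """
    rng = np.random.default_rng(spec.seed)
    dna = make_bdna(spec.dna_sequence, name=spec.name)
    z_center = (len(spec.dna_sequence) - 1) * RISE / 2.0
    protein = make_protein_arc(
        spec.protein_size, chain_id="A", z_center=z_center,
        phase=float(rng.uniform(0.0, 2.0 * np.pi)),
    )
    atoms = protein + dna.atoms
    cx = Complex(atoms, resolution=spec.resolution, method=spec.method,
                 name=spec.name)

    n = len(spec.dna_sequence)
    seq = spec.dna_sequence.upper()
    n_res = spec.protein_size
    for k, (ptype, dtype, distance, position) in enumerate(spec.planted_contacts):
        if not 0.0 < distance < 20.0:
            raise PlantingError(f"planted distance {distance} out of (0, 20)")
        if not 0 <= position < n:
            raise PlantingError(f"position {position} outside duplex")
        d_res, d_atom = dtype.split(".")
        ref_name = RESNAME[seq[position]]
        partner_name = RESNAME[COMPLEMENT[seq[position]]]
        if d_res == ref_name:
            chain, resnum = "B", position + 1
        elif d_res == partner_name:
            chain, resnum = "C", n - position
        else:
            raise PlantingError(
                f"contact {k}: {dtype} not present at position {position} "
                f"(pair {ref_name}/{partner_name})"
            )
        target = None
        for a in cx.atoms:
            if a.chain_id == chain and a.residue_number == resnum \
                    and a.atom_name == d_atom:
                target = a
                break
        if target is None:
            raise PlantingError(f"contact {k}: atom {dtype} missing")

        radial = np.array([target.coords[0], target.coords[1], 0.0])
        nr = np.linalg.norm(radial)
        direction = radial / nr if nr > 0.5 else np.array([1.0, 0.0, 0.0])
        planted_pos = target.coords + distance * direction

        p_res, p_atom = ptype.split(".")
        res_idx = (k + 1) * n_res // (len(spec.planted_contacts) + 1)
        res_num = max(1, min(n_res, res_idx + 1))
        # retype the carrier residue and relocate / add the planted atom
        carrier = [a for a in cx.atoms
                   if a.chain_id == "A" and a.residue_number == res_num]
        for a in carrier:
            a.residue_name = p_res
        existing = next((a for a in carrier if a.atom_name == p_atom), None)
        others = [a for a in cx.atoms if a is not existing]
        dmin = min(float(np.linalg.norm(a.coords - planted_pos))
                   for a in others)
        if dmin < 1.5:
            raise PlantingError(
                f"contact {k}: planted atom clashes ({dmin:.2f} A)"
            )
        if existing is not None:
            existing.coords = planted_pos
        else:
            anchor = next(i for i, a in enumerate(cx.atoms) if a is carrier[-1])
            cx.atoms.insert(anchor + 1, Atom(
                chain_id="A", residue_name=p_res, residue_number=res_num,
                atom_name=p_atom, element=p_atom[0], coords=planted_pos,
            ))
    return cx


def make_planted_kb_corpus(
    n: int, preference: str, seed: int = 0,
    probe_type: str = "ARG.NH1", flank: int = 4, run: int = 5,
) -> list[Complex]:
    """Toy complexes with a planted base preference for corpus building.

    Each complex carries a run of the preferred base in the middle of
    a random-flanked duplex.  The probe atom type is planted 3-4 A
    from the preferred base's discriminating major-groove atom at the
    center position and, by sequence design, stays >= 8 A from the
    discriminating atoms of the other three bases on the reference
    sense (the Watson-Crick partners of the planted run sit closer, but
    they are part of the planted pair signal itself).  Five additional
    alanine CB atoms are planted 4.2-4.4 A from backbone phosphate
    oxygens of the central run so that every complex clears the
    contact-residue admission filter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    preference = preference.upper()
    if preference not in BASES:
        raise ValueError("preference must be one of A, C, G, T")
    rng = np.random.default_rng(seed)
    others = [b for b in BASES if b != preference]
    out = []
    center = flank + run // 2
    disc = DISCRIMINATING_ATOM[preference]
    pref_res = RESNAME[preference]
    for k in range(n):
        seq = (
            "".join(rng.choice(others, size=flank))
            + preference * run
            + "".join(rng.choice(others, size=flank))
        )
        contacts = [
            (probe_type, f"{pref_res}.{disc}",
             float(rng.uniform(3.2, 3.8)), center),
        ]
        for off in range(-2, 3):
            contacts.append(
                ("ALA.CB", f"{pref_res}.OP1",
                 float(rng.uniform(4.2, 4.4)), center + off)
            )
        spec = FixtureSpec(
            dna_sequence=seq,
            protein_size=int(rng.integers(42, 60)),
            planted_contacts=tuple(contacts),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            name=f"planted-{preference}-{k}",
        )
        out.append(make_toy_complex(spec))
    return out
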