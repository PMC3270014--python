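"""DNA threading: in-silico base-pair substitution and PWM emission.

Assuming positions contribute independently to the binding free energy,
the energy of base alpha at duplex position i,

    dG_i(alpha) = sum of pair potentials between every protein heavy
                  atom and every heavy atom of the two nucleotides of
                  the substituted Watson-Crick pair, within r_cut,

is evaluated by replacing the reference-strand base at i with alpha and
its partner with the complement.  Backbone coordinates never move; the
base moiety is rebuilt from the idealized base library by superposing
the shared glycosidic frame (C1', glycosidic N, ring anchor).  Residue
names are updated so atom typing follows the new identity, which also
changes the backbone atom *types* (the 82-type scheme distinguishes
DA.P from DG.P) while leaving backbone geometry untouched.

Column probabilities follow a Boltzmann rule with temperature-like
divisor beta (default 15):

    p_i(alpha) = exp(-dG_i(alpha) / beta) / sum_alpha' exp(...)

computed with a max-shift for numerical stability.  Positions the
protein does not reach within r_cut get uniform columns and are
flagged as non-contacted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import baselib
from .atomtypes import dna_type_index, normalize_atom_name, normalize_residue_name
from .baselib import BASES, COMPLEMENT, RESNAME
from .knowledgebase import _bin_indices, _typed_arrays
from .potential import PairPotential
from .pwm import PWM
from .structio import Atom, Complex, DuplexInfo, StructureError

__all__ = [
    "PositionEnergies",
    "substitute_base_pair",
    "position_energies",
    "predict_pwm",
]

logger = logging.getLogger(__name__)

_BACKBONE_NAMES = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                   "C3'", "O3'", "C2'", "C1'"}


@dataclass
class PositionEnergies:
    """Threading energies of the four bases at one duplex position."""

    position: int
    energies: dict[str, float]
    contacted: bool

    def as_vector(self) -> np.ndarray:
        return np.array([self.energies[b] for b in BASES])


def _substitute_residue(cx: Complex, key: tuple[str, int], base: str) -> None:
    """Replace one nucleotide's base moiety in place (backbone fixed)."""
    res_atoms = [a for a in cx.atoms if a.residue_key == key]
    if not res_atoms:
        raise StructureError(f"residue {key} not found")
    old_resname = normalize_residue_name(res_atoms[0].residue_name)
    old_base = baselib.BASE_OF_RESNAME.get(old_resname)
    if old_base is None:
        raise StructureError(f"residue {key} is not a standard nucleotide")
    fnames = baselib.frame_atom_names(old_base)
    frame_coords = {}
    for a in res_atoms:
        n = normalize_atom_name(a.atom_name)
        if n in fnames:
            frame_coords[n] = a.coords
    if len(frame_coords) != 3:
        missing = set(fnames) - set(frame_coords)
        raise StructureError(f"residue {key}: frame atoms missing: {missing}")
    R, t = baselib.frame_transform(
        old_base, *(frame_coords[n] for n in fnames)
    )

    new_resname = RESNAME[base]
    template = res_atoms[0]
    kept: list[Atom] = []
    for a in res_atoms:
        if normalize_atom_name(a.atom_name) in _BACKBONE_NAMES:
            a.residue_name = new_resname
            kept.append(a)
    placed = [
        Atom(
            chain_id=template.chain_id,
            residue_name=new_resname,
            residue_number=template.residue_number,
            atom_name=name,
            element=name[0],
            coords=xyz @ R.T + t,
            occupancy=1.0,
        )
        for name, xyz in baselib.base_atoms(base)
    ]
    # splice: keep global atom order, residue atoms replaced contiguously
    first = next(i for i, a in enumerate(cx.atoms) if a.residue_key == key)
    cx.atoms = [a for a in cx.atoms if a.residue_key != key]
    cx.atoms[first:first] = kept + placed


def substitute_base_pair(
    cx: Complex, duplex: DuplexInfo, i: int, base: str
) -> Complex:
    """Thread base ``base`` (and its complement) into pair ``i``.

    Position ``i`` indexes the duplex pairs 5'->3' on the reference
    strand.  Returns a new complex; the input is not modified.
    """
    if base not in BASES:
        raise ValueError(f"base must be one of {BASES}, got {base!r}")
    if not 0 <= i < len(duplex.pairs):
        raise StructureError(
            f"position {i} is not a paired position (0..{len(duplex.pairs) - 1})"
        )
    ref_key, partner_key = duplex.pairs[i]
    out = cx.copy()
    _substitute_residue(out, ref_key, base)
    _substitute_residue(out, partner_key, COMPLEMENT[base])
    return out


def _nucleotide_energy(cx: Complex, keys: set[tuple[str, int]],
                       pot: PairPotential) -> tuple[float, bool]:
    """(energy, any pair within r_cut) restricted to the given residues."""
    pc, pi, _ = _typed_arrays(cx, "protein")
    nuc = [a for a in cx.atoms_of_kind("dna") if a.residue_key in keys]
    coords, idx = [], []
    for a in nuc:
        t = dna_type_index(a.residue_name, a.atom_name)
        if t is not None:
            coords.append(a.coords)
            idx.append(t)
    if len(pc) == 0 or not coords:
        return 0.0, False
    dc = np.array(coords)
    di = np.array(idx, dtype=np.int64)
    d = cdist(pc, dc)
    bins = _bin_indices(d)
    ii, jj = np.nonzero(bins >= 0)
    if len(ii) == 0:
        return 0.0, False
    return float(pot.u[pi[ii], di[jj], bins[ii, jj]].sum()), True


def position_energies(
    cx: Complex, duplex: DuplexInfo, i: int, pot: PairPotential
) -> PositionEnergies:
    """Threading energies dG_i(alpha) for all four bases at position i."""
    keys = set(duplex.pairs[i])
    energies: dict[str, float] = {}
    contacted = False
    for base in BASES:
        sub = substitute_base_pair(cx, duplex, i, base)
        e, touched = _nucleotide_energy(sub, keys, pot)
        energies[base] = e
        contacted = contacted or touched
    if not contacted:
        # no protein atom reaches any variant: energies are all zero
        energies = {b: 0.0 for b in BASES}
    return PositionEnergies(position=i, energies=energies, contacted=contacted)


def boltzmann_column(energies: np.ndarray, beta: float) -> np.ndarray:
    """exp(-dG/beta), max-shifted and normalized."""
    x = -np.asarray(energies, dtype=float) / beta
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


def predict_pwm(
    cx: Complex,
    duplex: DuplexInfo,
    pot: PairPotential,
    beta: float | None = None,
    trim_to_contacts: bool = False,
    name: str = "",
) -> tuple[PWM, list[PositionEnergies]]:
    """Thread every paired position and emit the PWM.

    Returns the PWM (columns 5'->3' on the reference strand, order
    A, C, G, T) and the per-position energies.  With
    ``trim_to_contacts`` the matrix is cut down to the span between the
    first and last contacted position; by default all positions are
    reported with contact flags.
    """
    if not duplex.pairs:
        raise StructureError("duplex has no paired position")
    beta = pot.params.beta if beta is None else beta
    rows = []
    flags = []
    details: list[PositionEnergies] = []
    for i in range(len(duplex.pairs)):
        pe = position_energies(cx, duplex, i, pot)
        details.append(pe)
        rows.append(boltzmann_column(pe.as_vector(), beta))
        flags.append(pe.contacted)
    pwm = PWM(np.array(rows), name=name,
              reference_strand=duplex.reference_strand,
              contacted=np.array(flags), beta=beta)
    if trim_to_contacts and any(flags):
        idx = np.nonzero(flags)[0]
        pwm = pwm.slice(int(idx[0]), int(idx[-1]) + 1)
        details = details[int(idx[0]): int(idx[-1]) + 1]
    elif trim_to_contacts:
        logger.warning("no contacted position; PWM left untrimmed")
    return pwm, details
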