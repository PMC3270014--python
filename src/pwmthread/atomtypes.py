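"""Heavy-atom type vocabularies for the all-atom protein-DNA potential.

The potential distinguishes every heavy atom of the 20 standard amino
acids (167 protein types) and of the four deoxyribonucleotides including
the sugar-phosphate backbone (82 DNA types).  An atom type is simply the
pair ``(residue_name, atom_name)`` written ``"ARG.NH1"`` / ``"DG.N7"``.

Atoms outside the vocabulary (solvent, ions, modified residues, OXT,
terminal-phosphate oxygens such as O5T) are not typed and are skipped by
the counting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AtomType",
    "PROTEIN_RESIDUES",
    "DNA_RESIDUES",
    "PROTEIN_TYPES",
    "DNA_TYPES",
    "PROTEIN_INDEX",
    "DNA_INDEX",
    "N_PROTEIN_TYPES",
    "N_DNA_TYPES",
    "normalize_atom_name",
    "normalize_residue_name",
    "assign_type",
    "protein_type_index",
    "dna_type_index",
]

_BACKBONE = ("N", "CA", "C", "O")

# Side-chain heavy atoms per standard amino acid (PDB v3 nomenclature,
# no OXT, no hydrogens).  Together with the 4 backbone atoms this gives
# the 167-type protein vocabulary.
_SIDECHAINS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

PROTEIN_RESIDUES: tuple[str, ...] = tuple(sorted(_SIDECHAINS))

# Sugar-phosphate backbone common to the four deoxyribonucleotides.
DNA_BACKBONE: tuple[str, ...] = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
)

# Base-moiety heavy atoms (PDB v3: thymine methyl is C7).
DNA_BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "DA": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "DC": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "DG": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "DT": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
}

DNA_RESIDUES: tuple[str, ...] = ("DA", "DC", "DG", "DT")


@dataclass(frozen=True)
class AtomType:
    """A (residue, atom) pair, e.g. ARG.NH1 or DG.N7."""

    residue_name: str
    atom_name: str

    @property
    def label(self) -> str:
        return f"{self.residue_name}.{self.atom_name}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _build_vocab() -> tuple[tuple[str, ...], tuple[str, ...]]:
    prot = []
    for res in PROTEIN_RESIDUES:
        for name in _BACKBONE + _SIDECHAINS[res]:
            prot.append(f"{res}.{name}")
    dna = []
    for res in DNA_RESIDUES:
        for name in DNA_BACKBONE + DNA_BASE_ATOMS[res]:
            dna.append(f"{res}.{name}")
    return tuple(prot), tuple(dna)


PROTEIN_TYPES, DNA_TYPES = _build_vocab()
N_PROTEIN_TYPES = len(PROTEIN_TYPES)   # 167
N_DNA_TYPES = len(DNA_TYPES)           # 82

PROTEIN_INDEX: dict[str, int] = {t: i for i, t in enumerate(PROTEIN_TYPES)}
DNA_INDEX: dict[str, int] = {t: i for i, t in enumerate(DNA_TYPES)}

# legacy / variant atom-name spellings -> PDB v3
_ATOM_ALIASES = {
    "O1P": "OP1",
    "O2P": "OP2",
    "C5M": "C7",   # thymine methyl, old spelling
    "C5A": "C7",
}

# legacy single-letter nucleotide codes -> DNA residue codes
_RESIDUE_ALIASES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


def normalize_atom_name(name: str) -> str:
    name = name.strip().replace("*", "'")
    return _ATOM_ALIASES.get(name, name)


def normalize_residue_name(name: str) -> str:
    name = name.strip()
    return _RESIDUE_ALIASES.get(name, name)


def assign_type(residue_name: str, atom_name: str) -> AtomType | None:
    """Look up the vocabulary type of an atom, or ``None`` if untyped.

    Nomenclature is normalized first (``O1P`` -> ``OP1``, ``C1*`` ->
    ``C1'``, single-letter nucleotides -> ``DA``/``DC``/``DG``/``DT``).
    """
    res = normalize_residue_name(residue_name)
    name = normalize_atom_name(atom_name)
    label = f"{res}.{name}"
    if label in PROTEIN_INDEX or label in DNA_INDEX:
        return AtomType(res, name)
    return None


def protein_type_index(residue_name: str, atom_name: str) -> int | None:
    res = normalize_residue_name(residue_name)
    name = normalize_atom_name(atom_name)
    return PROTEIN_INDEX.get(f"{res}.{name}")


def dna_type_index(residue_name: str, atom_name: str) -> int | None:
    res = normalize_residue_name(residue_name)
    name = normalize_atom_name(atom_name)
    return DNA_INDEX.get(f"{res}.{name}")
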