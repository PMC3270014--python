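"""PDB structure I/O, chain classification, duplex detection and filters.

This module owns the in-memory :class:`Complex` used everywhere else:
a flat list of heavy atoms partitioned into chains that are classified
as protein, DNA or other by residue composition.  It also implements
the complex-selection rules used both to admit structures into the
contact knowledgebase and to qualify template complexes:

* X-ray structure with resolution better than 3.0 A,
* (knowledgebase only) exactly one double-stranded DNA,
* >=6 Watson-Crick base pairs and <30% unpaired DNA residues,
* a protein chain with >=5 contact residues (heavy atom within 4.5 A
  of DNA),
* a protein chain with >=40 residues.

Watson-Crick pairing is operationalized as complementarity plus an
N1(purine)-N3(pyrimidine) distance of at most 3.5 A; no angular test is
applied, which is adequate for near-ideal duplexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import gemmi
import numpy as np

from .atomtypes import (
    DNA_RESIDUES,
    PROTEIN_RESIDUES,
    normalize_atom_name,
    normalize_residue_name,
)

__all__ = [
    "Atom",
    "Residue",
    "Complex",
    "DuplexInfo",
    "FilterProfile",
    "KNOWLEDGEBASE_PROFILE",
    "TEMPLATE_PROFILE",
    "StructureError",
    "read_structure",
    "write_structure",
    "detect_duplex",
    "detect_duplexes",
    "contact_residues",
    "passes_filters",
]

logger = logging.getLogger(__name__)

_PURINES = {"DA": "N1", "DG": "N1"}
_PYRIMIDINES = {"DC": "N3", "DT": "N3"}
_COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG"}

PAIRING_DISTANCE = 3.5  # A, max N1(purine)-N3(pyrimidine) separation


class StructureError(ValueError):
    """Raised for unusable or inconsistent structural input."""


@dataclass
class Atom:
    """One heavy atom with PDB-style identity and coordinates in A."""

    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.atom_name}: bad coordinates")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Residue:
    chain_id: str
    name: str
    number: int
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.number)

    def atom(self, name: str) -> Atom | None:
        name = normalize_atom_name(name)
        for a in self.atoms:
            if normalize_atom_name(a.atom_name) == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


def _residue_kind(name: str) -> str:
    name = normalize_residue_name(name)
    if name in PROTEIN_RESIDUES:
        return "protein"
    if name in DNA_RESIDUES:
        return "dna"
    return "other"


class Complex:
    """A set of heavy atoms grouped into classified chains.

    Chains are classified by majority residue composition; residues that
    are neither standard amino acids nor DA/DC/DG/DT count as "other"
    and such chains are retained but ignored by the potential.
    """

    def __init__(
        self,
        atoms: list[Atom],
        resolution: float | None = None,
        method: str | None = None,
        model_index: int = 0,
        name: str = "",
    ) -> None:
        self.atoms = list(atoms)
        self.resolution = resolution
        self.method = method
        self.model_index = model_index
        self.name = name

    # -- grouping -------------------------------------------------------

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        out: list[Residue] = []
        current: Residue | None = None
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if current is None or current.key != a.residue_key:
                current = Residue(a.chain_id, a.residue_name, a.residue_number, [])
                out.append(current)
            current.atoms.append(a)
        return out

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def chains(self) -> dict[str, str]:
        """Mapping chain_id -> polymer kind in {protein, dna, other}."""
        kinds: dict[str, str] = {}
        for cid in self.chain_ids():
            votes = {"protein": 0, "dna": 0, "other": 0}
            for res in self.residues(cid):
                votes[_residue_kind(res.name)] += 1
            kinds[cid] = max(votes, key=lambda k: (votes[k], k != "other"))
        return kinds

    def chain_kind(self, chain_id: str) -> str:
        return self.chains[chain_id]

    def protein_chain_ids(self) -> list[str]:
        return [c for c, k in self.chains.items() if k == "protein"]

    def dna_chain_ids(self) -> list[str]:
        return [c for c, k in self.chains.items() if k == "dna"]

    def atoms_of_kind(self, kind: str) -> list[Atom]:
        wanted = {c for c, k in self.chains.items() if k == kind}
        return [a for a in self.atoms if a.chain_id in wanted]

    def coords(self, atoms: list[Atom] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in atoms])

    def copy(self) -> "Complex":
        return Complex(
            [replace(a, coords=a.coords.copy()) for a in self.atoms],
            resolution=self.resolution,
            method=self.method,
            model_index=self.model_index,
            name=self.name,
        )

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class DuplexInfo:
    """Watson-Crick pairing of one double-stranded DNA region."""

    pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    n_paired: int
    n_unpaired: int
    reference_strand: str
    # residue names of the reference-strand side, 5'->3'
    reference_sequence: str = ""

    def partner_of(self, key: tuple[str, int]) -> tuple[str, int] | None:
        for a, b in self.pairs:
            if a == key:
                return b
            if b == key:
                return a
        return None


@dataclass(frozen=True)
class FilterProfile:
    """Structure-selection thresholds for knowledgebase/template admission."""

    max_resolution: float = 3.0
    require_single_dsdna: bool = True
    min_paired_bases: int = 6
    max_unpaired_fraction: float = 0.30
    min_contact_residues: int = 5
    contact_cutoff: float = 4.5
    min_chain_length: int = 40
    require_xray: bool = True
    reject_missing_method: bool = True


KNOWLEDGEBASE_PROFILE = FilterProfile()
TEMPLATE_PROFILE = FilterProfile(
    require_single_dsdna=False, reject_missing_method=False
)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_structure(pdb_text: str, model_index: int = 0, name: str = "") -> Complex:
    """Parse PDB-format text into a heavy-atom :class:`Complex`.

    Only the requested model is kept (default: first).  Hydrogens and
    deuteriums are stripped; alternate locations are resolved to the
    highest-occupancy conformer (ties: first in file order).
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no models in structure")
    if model_index >= len(st):
        raise StructureError(f"model {model_index} not present ({len(st)} models)")
    model = st[model_index]

    atoms: list[Atom] = []
    # altloc resolution: keep best occupancy per (chain, resnum, resname, atom)
    best: dict[tuple, int] = {}
    for chain in model:
        for res in chain:
            for at in res:
                if at.element.name in ("H", "D"):
                    continue
                altloc = "" if at.altloc in ("\x00", " ", "") else at.altloc
                atom = Atom(
                    chain_id=chain.name,
                    residue_name=res.name.strip(),
                    residue_number=res.seqid.num,
                    atom_name=at.name.strip(),
                    element=at.element.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    altloc=altloc,
                )
                key = (chain.name, res.seqid.num, res.name, at.name.strip())
                if key in best:
                    idx = best[key]
                    if atom.occupancy > atoms[idx].occupancy:
                        atoms[idx] = atom
                else:
                    best[key] = len(atoms)
                    atoms.append(atom)

    if not atoms:
        raise StructureError("structure contains no heavy atoms")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    method = st.info["_exptl.method"] if "_exptl.method" in st.info else None
    cx = Complex(atoms, resolution=resolution, method=method,
                 model_index=model_index, name=name or st.name)
    for cid, kind in cx.chains.items():
        if kind == "other":
            logger.info("chain %s classified as 'other' (non-standard residues)", cid)
    return cx


def write_structure(cx: Complex) -> str:
    """Render a :class:`Complex` as PDB-format text (standard ATOM records)."""
    st = gemmi.Structure()
    st.name = cx.name or "complex"
    if cx.resolution is not None:
        st.resolution = cx.resolution
    if cx.method:
        st.info["_exptl.method"] = cx.method
    model = gemmi.Model(1)
    for cid in cx.chain_ids():
        chain = gemmi.Chain(cid)
        for res in cx.residues(cid):
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.number, " ")
            for a in res.atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.occ = a.occupancy
                at.pos = gemmi.Position(*a.coords)
                if a.altloc:
                    at.altloc = a.altloc
                r.add_atom(at)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# duplex detection
# ---------------------------------------------------------------------------

def _wc_anchor(res: Residue) -> tuple[str, np.ndarray] | None:
    """Return ('purine'|'pyrimidine', anchor coords) for a DNA residue."""
    name = normalize_residue_name(res.name)
    if name in _PURINES:
        a = res.atom("N1")
        return ("purine", a.coords) if a is not None else None
    if name in _PYRIMIDINES:
        a = res.atom("N3")
        return ("pyrimidine", a.coords) if a is not None else None
    return None


def _all_pairs(cx: Complex) -> list[tuple[Residue, Residue, float]]:
    """All complementary residue pairs with N1-N3 within the cutoff."""
    dna_res = [r for cid in cx.dna_chain_ids() for r in cx.residues(cid)]
    anchors = []
    for r in dna_res:
        info = _wc_anchor(r)
        if info is not None:
            anchors.append((r, *info))
    cands = []
    for i, (ri, kindi, pi) in enumerate(anchors):
        for rj, kindj, pj in anchors[i + 1:]:
            if kindi == kindj:
                continue
            if _COMPLEMENT[normalize_residue_name(ri.name)] != normalize_residue_name(rj.name):
                continue
            d = float(np.linalg.norm(pi - pj))
            if d <= PAIRING_DISTANCE:
                cands.append((ri, rj, d))
    # greedy matching by ascending distance; each residue in <=1 pair
    cands.sort(key=lambda t: t[2])
    used: set[tuple[str, int]] = set()
    pairs = []
    for ri, rj, d in cands:
        if ri.key in used or rj.key in used:
            continue
        used.add(ri.key)
        used.add(rj.key)
        pairs.append((ri, rj, d))
    return pairs


def detect_duplexes(cx: Complex) -> list[DuplexInfo]:
    """Group Watson-Crick pairs into duplexes by their chain pair.

    Returns one :class:`DuplexInfo` per (chain, chain) grouping holding
    at least one base pair, largest first.  ``n_unpaired`` counts, for
    each group, the DNA residues of the whole complex outside any pair.
    """
    if not cx.dna_chain_ids():
        raise StructureError("complex contains no DNA chain")
    pairs = _all_pairs(cx)
    total_dna = sum(len(cx.residues(cid)) for cid in cx.dna_chain_ids())
    n_unpaired = total_dna - 2 * len(pairs)

    groups: dict[tuple[str, str], list[tuple[Residue, Residue, float]]] = {}
    for ri, rj, d in pairs:
        key = tuple(sorted((ri.chain_id, rj.chain_id)))
        groups.setdefault(key, []).append((ri, rj, d))

    duplexes = []
    for key in sorted(groups):
        members = groups[key]
        ref = min(key)
        ordered = []
        for ri, rj, _ in members:
            if ri.chain_id != ref or (rj.chain_id == ref and rj.number < ri.number):
                ri, rj = rj, ri
            ordered.append((ri, rj))
        ordered.sort(key=lambda p: p[0].number)
        seq = "".join(normalize_residue_name(ri.name)[-1] for ri, _ in ordered)
        duplexes.append(
            DuplexInfo(
                pairs=[(ri.key, rj.key) for ri, rj in ordered],
                n_paired=len(ordered),
                n_unpaired=n_unpaired,
                reference_strand=ref,
                reference_sequence=seq,
            )
        )
    duplexes.sort(key=lambda d: (-d.n_paired, d.reference_strand))
    return duplexes


def detect_duplex(cx: Complex, reference_strand: str | None = None) -> DuplexInfo:
    """Find the main Watson-Crick duplex of the complex.

    A residue pair counts as paired when the bases are complementary and
    the N1(purine)-N3(pyrimidine) distance is at most 3.5 A.  The
    reference strand defaults to the lexicographically first DNA chain.
    """
    duplexes = detect_duplexes(cx)
    if not duplexes:
        total_dna = sum(len(cx.residues(cid)) for cid in cx.dna_chain_ids())
        ref = reference_strand or sorted(cx.dna_chain_ids())[0]
        return DuplexInfo(pairs=[], n_paired=0, n_unpaired=total_dna,
                          reference_strand=ref)
    if reference_strand is not None:
        for d in duplexes:
            if reference_strand in {c for p in d.pairs for c, _ in p} or \
                    d.reference_strand == reference_strand:
                if d.reference_strand != reference_strand:
                    d = _reorient(d, reference_strand, cx)
                return d
        raise StructureError(f"no duplex involves chain {reference_strand!r}")
    return duplexes[0]


def _reorient(d: DuplexInfo, ref: str, cx: Complex) -> DuplexInfo:
    """Swap pair order so the requested chain is the reference strand."""
    flipped = [(b, a) if b[0] == ref else (a, b) for a, b in d.pairs]
    flipped.sort(key=lambda p: p[0][1])
    names = {r.key: r.name for cid in cx.dna_chain_ids() for r in cx.residues(cid)}
    seq = "".join(normalize_residue_name(names[a])[-1] for a, _ in flipped)
    return DuplexInfo(pairs=flipped, n_paired=d.n_paired, n_unpaired=d.n_unpaired,
                      reference_strand=ref, reference_sequence=seq)


# ---------------------------------------------------------------------------
# contacts and filters
# ---------------------------------------------------------------------------

def contact_residues(cx: Complex, cutoff: float = 4.5) -> set[tuple[str, int]]:
    """Protein residues with any heavy atom within ``cutoff`` A of DNA."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot = cx.atoms_of_kind("protein")
    dna = cx.atoms_of_kind("dna")
    if not prot or not dna:
        return set()
    pc = cx.coords(prot)
    dc = cx.coords(dna)
    from scipy.spatial import cKDTree

    tree = cKDTree(dc)
    dmin, _ = tree.query(pc, k=1)
    return {prot[i].residue_key for i in np.nonzero(dmin <= cutoff)[0]}


def passes_filters(cx: Complex, profile: FilterProfile) -> tuple[bool, list[str]]:
    """Evaluate every selection criterion; return (ok, all failure reasons)."""
    failures: list[str] = []

    if profile.require_xray:
        if cx.method is None:
            if profile.reject_missing_method:
                failures.append("method: experimental method not recorded")
        elif "X-RAY" not in cx.method.upper():
            failures.append(f"method: not X-ray ({cx.method})")

    if cx.resolution is None:
        if profile.reject_missing_method:
            failures.append("resolution: not recorded")
    elif not cx.resolution < profile.max_resolution:
        failures.append(
            f"resolution: {cx.resolution:.2f} A not better than "
            f"{profile.max_resolution:.1f} A"
        )

    if not cx.dna_chain_ids():
        failures.append("dna: no DNA chain")
        return (False, failures)
    if not cx.protein_chain_ids():
        failures.append("protein: no protein chain")
        return (False, failures)

    duplexes = [d for d in detect_duplexes(cx) if d.n_paired >= 2]
    if profile.require_single_dsdna and len(duplexes) != 1:
        failures.append(f"dsdna: expected exactly one duplex, found {len(duplexes)}")

    main = duplexes[0] if duplexes else None
    n_paired = main.n_paired if main else 0
    if n_paired < profile.min_paired_bases:
        failures.append(
            f"min_paired_bases: {n_paired} < {profile.min_paired_bases}"
        )
    total_dna = sum(len(cx.residues(cid)) for cid in cx.dna_chain_ids())
    n_unpaired = main.n_unpaired if main else total_dna
    if total_dna and not n_unpaired / total_dna < profile.max_unpaired_fraction:
        failures.append(
            f"unpaired_fraction: {n_unpaired}/{total_dna} not below "
            f"{profile.max_unpaired_fraction:.0%}"
        )

    contacts = contact_residues(cx, profile.contact_cutoff)
    per_chain: dict[str, int] = {}
    for cid, _num in contacts:
        per_chain[cid] = per_chain.get(cid, 0) + 1
    if not per_chain or max(per_chain.values()) < profile.min_contact_residues:
        best = max(per_chain.values()) if per_chain else 0
        failures.append(
            f"contact_residues: best chain has {best} < "
            f"{profile.min_contact_residues}"
        )

    lengths = [len(cx.residues(cid)) for cid in cx.protein_chain_ids()]
    if not lengths or max(lengths) < profile.min_chain_length:
        failures.append(
            f"chain_length: longest protein chain "
            f"{max(lengths) if lengths else 0} < {profile.min_chain_length}"
        )

    return (not failures, failures)
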