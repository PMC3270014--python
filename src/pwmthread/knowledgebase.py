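"""Distance-binned protein-DNA atom-pair counts (the "knowledgebase").

Counts N_obs(i, j, r) record, over a filtered collection of protein-DNA
complexes, how often protein atom type i and DNA atom type j are found
at a distance within bin r.  Bins are labelled by their upper edge
r in {3, 4, ..., 10} A with widths dr(3) = 3 and dr(r>3) = 1, interval
convention (r - dr, r]: a distance of exactly 3.0 falls in bin 3 and
exactly 10.0 in bin 10; anything above 10 A is not counted.

Each protein-atom/DNA-atom pair is counted exactly once with the
protein atom always in the first role; intra-protein and intra-DNA
pairs never contribute.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .atomtypes import (
    DNA_TYPES,
    N_DNA_TYPES,
    N_PROTEIN_TYPES,
    PROTEIN_TYPES,
    DNA_INDEX,
    PROTEIN_INDEX,
    dna_type_index,
    protein_type_index,
)
from .structio import Complex, FilterProfile, KNOWLEDGEBASE_PROFILE, passes_filters

__all__ = [
    "BIN_UPPER_EDGES",
    "BIN_WIDTHS",
    "N_BINS",
    "distance_bin",
    "bin_index",
    "Knowledgebase",
    "count_pairs",
    "build_knowledgebase",
    "save_kb",
    "load_kb",
    "KnowledgebaseError",
]

logger = logging.getLogger(__name__)

BIN_UPPER_EDGES = (3, 4, 5, 6, 7, 8, 9, 10)
BIN_WIDTHS = (3, 1, 1, 1, 1, 1, 1, 1)
N_BINS = len(BIN_UPPER_EDGES)
R_CUT = 10.0


class KnowledgebaseError(ValueError):
    pass


def distance_bin(d: float) -> int | None:
    """Map a distance (A) to its bin label r, or None beyond 10 A.

    The bin for distance d is the unique r with r - dr < d <= r;
    all of (0, 3] collapses into bin 3.
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    if d > R_CUT:
        return None
    r = int(np.ceil(d))
    return max(r, 3)


def bin_index(r: int) -> int:
    """Position of bin label r within the count tensor's last axis."""
    try:
        return BIN_UPPER_EDGES.index(r)
    except ValueError:
        raise KnowledgebaseError(f"invalid bin label {r!r}") from None


def _bin_indices(d: np.ndarray) -> np.ndarray:
    """Vectorized bin-index computation; -1 marks out-of-range."""
    r = np.maximum(np.ceil(d), 3).astype(int)
    idx = r - 3
    idx[(d > R_CUT) | (d <= 0)] = -1
    return idx


@dataclass
class Knowledgebase:
    """The count tensor plus provenance of how it was built."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(
            (N_PROTEIN_TYPES, N_DNA_TYPES, N_BINS), dtype=np.int64
        )
    )
    n_complexes: int = 0
    n_protein_chains: int = 0
    profile: FilterProfile = KNOWLEDGEBASE_PROFILE
    provenance: str = ""

    def total(self) -> int:
        return int(self.counts.sum())

    def pair_total(self, i: int, j: int) -> int:
        return int(self.counts[i, j].sum())


def _typed_arrays(cx: Complex, kind: str) -> tuple[np.ndarray, np.ndarray, int]:
    """(coords, type indices) of vocabulary-typed atoms of a polymer kind.

    Returns the number of skipped (out-of-vocabulary) atoms as well.
    """
    lookup = protein_type_index if kind == "protein" else dna_type_index
    coords, idx, skipped = [], [], 0
    for a in cx.atoms_of_kind(kind):
        t = lookup(a.residue_name, a.atom_name)
        if t is None:
            skipped += 1
            continue
        coords.append(a.coords)
        idx.append(t)
    c = np.array(coords) if coords else np.zeros((0, 3))
    return c, np.array(idx, dtype=np.int64), skipped


def count_pairs(cx: Complex) -> dict[tuple[int, int, int], int]:
    """Count typed protein-DNA atom pairs within 10 A of one complex.

    Returns a sparse map {(protein type index, DNA type index, bin
    label): count}.  Every pair is counted once; atoms outside the
    type vocabulary are skipped (and logged).
    """
    pc, pi, pskip = _typed_arrays(cx, "protein")
    dc, di, dskip = _typed_arrays(cx, "dna")
    if pskip or dskip:
        logger.debug("count_pairs: skipped %d protein / %d DNA atoms "
                     "outside vocabulary", pskip, dskip)
    if len(pc) == 0 or len(dc) == 0:
        return {}
    d = cdist(pc, dc)
    bins = _bin_indices(d)
    ok = bins >= 0
    out: dict[tuple[int, int, int], int] = {}
    ii, jj = np.nonzero(ok)
    for a, b in zip(ii, jj):
        key = (int(pi[a]), int(di[b]), BIN_UPPER_EDGES[bins[a, b]])
        out[key] = out.get(key, 0) + 1
    return out


def accumulate(counts: np.ndarray, cx: Complex) -> None:
    """Add one complex's pair counts into a dense tensor, in place."""
    pc, pi, _ = _typed_arrays(cx, "protein")
    dc, di, _ = _typed_arrays(cx, "dna")
    if len(pc) == 0 or len(dc) == 0:
        return
    d = cdist(pc, dc)
    bins = _bin_indices(d)
    ii, jj = np.nonzero(bins >= 0)
    np.add.at(counts, (pi[ii], di[jj], bins[ii, jj]), 1)


def build_knowledgebase(
    complexes: list[Complex],
    profile: FilterProfile = KNOWLEDGEBASE_PROFILE,
    provenance: str = "",
) -> Knowledgebase:
    """Filter complexes, accumulate pair counts over the survivors.

    Rejected complexes are logged with their failure reasons.  Raises
    :class:`KnowledgebaseError` if no complex survives: an empty
    knowledgebase would make every pair uninformative.
    """
    counts = np.zeros((N_PROTEIN_TYPES, N_DNA_TYPES, N_BINS), dtype=np.int64)
    n_ok = 0
    n_chains = 0
    for k, cx in enumerate(complexes):
        ok, reasons = passes_filters(cx, profile)
        label = cx.name or f"complex[{k}]"
        if not ok:
            logger.info("rejected %s: %s", label, "; ".join(reasons))
            continue
        accumulate(counts, cx)
        n_ok += 1
        n_chains += len(cx.protein_chain_ids())
    if n_ok == 0:
        raise KnowledgebaseError("no complex passed the selection filters")
    return Knowledgebase(
        counts=counts,
        n_complexes=n_ok,
        n_protein_chains=n_chains,
        profile=profile,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# serialization: sparse TSV with header block and checksum
# ---------------------------------------------------------------------------

_FORMAT_VERSION = "1"


def _checksum(rows: list[str]) -> str:
    h = hashlib.sha256()
    for row in rows:
        h.update(row.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def save_kb(kb: Knowledgebase, path_or_file) -> None:
    """Write a knowledgebase as sparse TSV (bit-exact integer counts)."""
    rows = []
    nz = np.nonzero(kb.counts)
    for i, j, b in zip(*nz):
        rows.append(
            f"{PROTEIN_TYPES[i]}\t{DNA_TYPES[j]}\t{BIN_UPPER_EDGES[b]}\t"
            f"{kb.counts[i, j, b]}"
        )
    header = [
        f"#format\tpwmthread-kb\t{_FORMAT_VERSION}",
        f"#n_complexes\t{kb.n_complexes}",
        f"#n_protein_chains\t{kb.n_protein_chains}",
        f"#profile\t{kb.profile!r}",
        f"#provenance\t{kb.provenance}",
        f"#checksum\t{_checksum(rows)}",
    ]
    text = "\n".join(header + rows) + "\n"
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        with open(path_or_file, "w") as fh:
            fh.write(text)


def load_kb(path_or_file) -> Knowledgebase:
    """Load a knowledgebase written by :func:`save_kb` (lossless)."""
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file) as fh:
            text = fh.read()
    counts = np.zeros((N_PROTEIN_TYPES, N_DNA_TYPES, N_BINS), dtype=np.int64)
    meta = {"n_complexes": 0, "n_protein_chains": 0}
    provenance = ""
    profile_repr = ""
    stored_sum = None
    rows = []
    for line in io.StringIO(text):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split("\t")
            key = fields[0]
            if key == "format":
                if len(fields) < 3 or fields[1] != "pwmthread-kb" or \
                        fields[2] != _FORMAT_VERSION:
                    raise KnowledgebaseError(f"unsupported format header: {line!r}")
            elif key in meta:
                meta[key] = int(fields[1])
            elif key == "provenance":
                provenance = fields[1] if len(fields) > 1 else ""
            elif key == "profile":
                profile_repr = fields[1] if len(fields) > 1 else ""
            elif key == "checksum":
                stored_sum = fields[1]
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise KnowledgebaseError(f"malformed row: {line!r}")
        ptype, dtype, r, n = parts
        if ptype not in PROTEIN_INDEX:
            raise KnowledgebaseError(f"unknown protein atom type {ptype!r}")
        if dtype not in DNA_INDEX:
            raise KnowledgebaseError(f"unknown DNA atom type {dtype!r}")
        counts[PROTEIN_INDEX[ptype], DNA_INDEX[dtype], bin_index(int(r))] = int(n)
        rows.append(line)
    if stored_sum is None:
        raise KnowledgebaseError("missing checksum (truncated file?)")
    if _checksum(rows) != stored_sum:
        raise KnowledgebaseError("checksum mismatch (corrupt or truncated file)")
    profile = KNOWLEDGEBASE_PROFILE
    if profile_repr:
        try:
            profile = eval(profile_repr, {"FilterProfile": FilterProfile})
        except Exception:
            logger.warning("could not restore filter profile from %r", profile_repr)
    return Knowledgebase(
        counts=counts,
        n_complexes=meta["n_complexes"],
        n_protein_chains=meta["n_protein_chains"],
        profile=profile,
        provenance=provenance,
    )
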