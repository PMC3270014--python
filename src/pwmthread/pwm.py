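"""Position weight matrix container and interchange formats.

A PWM is an L x 4 column-stochastic matrix over the bases A, C, G, T,
read 5'->3' along a reference strand.  Columns produced by threading
carry a contact flag: positions with no protein atom within the
interaction cutoff are reported as uniform and flagged, since the
method can only infer preferences at physically contacted positions.

Supported formats: plain 4-column TSV, TRANSFAC-style matrix blocks
and JASPAR-style PFMs (count matrices are normalized on reading).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["PWM", "PWMError", "read_pwm", "parse_pwm",
           "write_tsv", "write_transfac", "write_jaspar"]

ALPHABET = "ACGT"
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


class PWMError(ValueError):
    pass


@dataclass
class PWM:
    """Column-stochastic base-probability matrix (columns: A, C, G, T)."""

    matrix: np.ndarray
    name: str = ""
    reference_strand: str = ""
    contacted: np.ndarray | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise PWMError("PWM must be an L x 4 matrix with L >= 1")
        if np.any(m < -1e-12):
            raise PWMError("PWM entries must be nonnegative")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise PWMError("PWM columns must sum to 1")
        # renormalize only when needed so that slicing and format
        # round-trips are bit-stable
        if np.any(m < 0) or np.any(np.abs(sums - 1.0) > 1e-12):
            m = np.clip(m, 0.0, None)
            m = m / m.sum(axis=1, keepdims=True)
        self.matrix = m
        if self.contacted is not None:
            self.contacted = np.asarray(self.contacted, dtype=bool)
            if self.contacted.shape != (len(self),):
                raise PWMError("contact flags must match PWM length")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        """Reverse column order and swap A<->T, C<->G."""
        m = self.matrix[::-1, ::-1].copy()
        flags = None if self.contacted is None else self.contacted[::-1].copy()
        return PWM(m, name=self.name, reference_strand=self.reference_strand,
                   contacted=flags, beta=self.beta)

    def consensus(self, tie_tol: float = 1e-9) -> str:
        """Per-column argmax consensus with IUPAC codes at ties."""
        out = []
        for col in self.matrix:
            top = col.max()
            letters = frozenset(ALPHABET[i] for i in range(4)
                                if col[i] >= top - tie_tol)
            out.append(_IUPAC[letters])
        return "".join(out)

    def slice(self, start: int, stop: int) -> "PWM":
        flags = None if self.contacted is None else self.contacted[start:stop]
        return PWM(self.matrix[start:stop].copy(), name=self.name,
                   reference_strand=self.reference_strand,
                   contacted=None if flags is None else flags.copy(),
                   beta=self.beta)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tsv(pwm: PWM) -> str:
    """Plain 4-column TSV (A C G T per row), 6 decimals."""
    lines = ["A\tC\tG\tT"]
    for col in pwm.matrix:
        lines.append("\t".join(f"{x:.6f}" for x in col))
    return "\n".join(lines) + "\n"


def write_transfac(pwm: PWM) -> str:
    """TRANSFAC-style matrix block (probabilities, 6 decimals)."""
    lines = [
        "AC  " + (pwm.name or "pwmthread"),
        "XX",
        "ID  " + (pwm.name or "pwmthread"),
        "XX",
        "P0      A      C      G      T",
    ]
    cons = pwm.consensus()
    for i, col in enumerate(pwm.matrix):
        vals = "  ".join(f"{x:8.6f}" for x in col)
        lines.append(f"{i + 1:02d}  {vals}  {cons[i]}")
    lines += ["XX", "//"]
    return "\n".join(lines) + "\n"


def write_jaspar(pwm: PWM) -> str:
    """JASPAR-style PFM with probability rows per base."""
    lines = [f">{pwm.name or 'pwmthread'}"]
    for i, b in enumerate(ALPHABET):
        vals = " ".join(f"{x:.6f}" for x in pwm.matrix[:, i])
        lines.append(f"{b} [ {vals} ]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _normalize_rows(rows: list[list[float]], name: str) -> PWM:
    m = np.array(rows, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise PWMError("expected 4 values (A C G T) per position")
    sums = m.sum(axis=1)
    if np.any(sums <= 0):
        raise PWMError("PWM has an all-zero column")
    return PWM(m / sums[:, None], name=name)


def _parse_jaspar(text: str) -> PWM:
    name = ""
    per_base: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if len(line) > 1 else ""
            continue
        m = re.match(r"^([ACGT])\s*\[?\s*([-0-9.eE+\s]+?)\s*\]?\s*$", line)
        if not m:
            raise PWMError(f"unparseable JASPAR line: {line!r}")
        per_base[m.group(1)] = [float(x) for x in m.group(2).split()]
    if set(per_base) != set(ALPHABET):
        raise PWMError("JASPAR block must contain A, C, G and T rows")
    lengths = {len(v) for v in per_base.values()}
    if len(lengths) != 1:
        raise PWMError("JASPAR rows have unequal lengths")
    rows = [[per_base[b][j] for b in ALPHABET]
            for j in range(lengths.pop())]
    return _normalize_rows(rows, name)


def _parse_transfac(text: str) -> PWM:
    name = ""
    rows = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line in ("XX", "//"):
            continue
        tag = line.split(maxsplit=1)
        if tag[0] in ("AC", "ID", "NA", "DE") and len(tag) > 1:
            name = name or tag[1].strip()
            continue
        if tag[0] in ("P0", "PO"):
            continue
        m = re.match(r"^\s*\d+\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)", line)
        if m:
            rows.append([float(m.group(k)) for k in range(1, 5)])
    if not rows:
        raise PWMError("no matrix rows found in TRANSFAC block")
    return _normalize_rows(rows, name)


def _parse_tsv(text: str) -> PWM:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,\s]+", line)
        if parts[:4] == ["A", "C", "G", "T"]:
            continue
        try:
            vals = [float(x) for x in parts]
        except ValueError:
            raise PWMError(f"unparseable TSV line: {line!r}") from None
        if len(vals) != 4:
            raise PWMError("expected 4 columns (A C G T) per line")
        rows.append(vals)
    if not rows:
        raise PWMError("empty PWM text")
    return _normalize_rows(rows, "")


def parse_pwm(text: str, fmt: str | None = None) -> PWM:
    """Parse a PWM from TSV, TRANSFAC or JASPAR text (auto-sniffed)."""
    if fmt is not None:
        return {"tsv": _parse_tsv, "transfac": _parse_transfac,
                "jaspar": _parse_jaspar}[fmt](text)
    stripped = text.lstrip()
    if stripped.startswith(">"):
        return _parse_jaspar(text)
    if re.search(r"^(P0|PO)\b", text, flags=re.MULTILINE) or \
            re.search(r"^(AC|ID)\s", text, flags=re.MULTILINE):
        return _parse_transfac(text)
    return _parse_tsv(text)


def read_pwm(path, fmt: str | None = None) -> PWM:
    with open(path) as fh:
        return parse_pwm(fh.read(), fmt=fmt)
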