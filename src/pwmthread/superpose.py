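"""Rigid superposition: build the synthetic protein-DNA complex.

Given an unbound query protein, a template protein-DNA complex and a
rigid transform (typically the rotation matrix reported by a structure
alignment tool such as TM-align), the synthetic complex is formed by
removing the template's protein chains and splicing in the transformed
query protein; the template DNA is never touched.

The matrix-file dialect is the structure-alignment tool's: three data
rows, each "i  t(i)  u(i,1)  u(i,2)  u(i,3)", applying x' = t + U x.
When only a residue correspondence is available, a least-squares
(Kabsch) transform can be computed instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from string import ascii_uppercase, ascii_lowercase, digits

import numpy as np

from .structio import Complex, StructureError

__all__ = [
    "Transform",
    "TransformError",
    "parse_matrix_file",
    "write_matrix_file",
    "kabsch",
    "apply_transform",
    "build_superimposed_complex",
]

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-6


class TransformError(ValueError):
    pass


@dataclass(frozen=True)
class Transform:
    """A proper rigid motion x' = t + U x (U: rotation, t: translation, A)."""

    U: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "t", t)
        if U.shape != (3, 3) or t.shape != (3,):
            raise TransformError("U must be 3x3 and t a 3-vector")
        if np.abs(U.T @ U - np.eye(3)).max() > _ORTHO_TOL:
            raise TransformError("U is not orthogonal within tolerance")
        if abs(np.linalg.det(U) - 1.0) > _ORTHO_TOL:
            raise TransformError("U is not a proper rotation (det != +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.U.T + self.t

    def inverse(self) -> "Transform":
        return Transform(self.U.T, -self.U.T @ self.t)

    def compose(self, other: "Transform") -> "Transform":
        """self after other: x -> self(other(x))."""
        return Transform(self.U @ other.U, self.U @ other.t + self.t)


def parse_matrix_file(text: str) -> Transform:
    """Parse a rotation-matrix file in the alignment tool's dialect.

    Data rows are identified as lines whose first field is an integer
    row index followed by four floats: t(i), u(i,1), u(i,2), u(i,3).
    """
    rows: list[list[float]] = []
    for line in text.splitlines():
        fields = line.split()
        if len(fields) < 5:
            continue
        try:
            int(fields[0])
            values = [float(x) for x in fields[1:5]]
        except ValueError:
            continue
        rows.append(values)
        if len(rows) == 3:
            break
    if len(rows) != 3:
        raise TransformError("expected three 'i t u1 u2 u3' data rows")
    m = np.array(rows)
    return Transform(U=m[:, 1:4], t=m[:, 0])


def write_matrix_file(tf: Transform, comment: str = "") -> str:
    """Write a transform in the same dialect that parse_matrix_file reads."""
    lines = []
    if comment:
        lines.append(f"------ {comment} ------")
    lines.append(" m               t[m]        u[m][0]        u[m][1]        u[m][2]")
    for i in range(3):
        lines.append(
            f" {i} {tf.t[i]: 18.10f} {tf.U[i, 0]: 14.10f}"
            f" {tf.U[i, 1]: 14.10f} {tf.U[i, 2]: 14.10f}"
        )
    lines.append("")
    lines.append("Code for rotating structure A from (x,y,z) to (X,Y,Z):")
    lines.append("   X = t[0] + u[0][0]*x + u[0][1]*y + u[0][2]*z")
    return "\n".join(lines) + "\n"


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid transform of ``moving`` onto ``fixed``.

    Returns the proper-rotation transform and the residual RMSD.
    Requires >=3 non-collinear point pairs.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise TransformError("point lists must be matching (n, 3) arrays")
    n = len(moving)
    if n < 3:
        raise TransformError("at least 3 point pairs required")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    h = a.T @ b
    v, s, wt = np.linalg.svd(h)
    # collinear inputs leave the rotation about the line undetermined
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise TransformError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(wt.T @ v.T))
    diag = np.diag([1.0, 1.0, d])
    U = wt.T @ diag @ v.T
    t = fc - U @ mc
    tf = Transform(U, t)
    rmsd = float(np.sqrt(((tf.apply(moving) - fixed) ** 2).sum() / n))
    return tf, rmsd


def apply_transform(cx: Complex, tf: Transform) -> Complex:
    """Return a copy of the complex with every atom moved by tf."""
    out = cx.copy()
    for a in out.atoms:
        a.coords = tf.apply(a.coords)
    return out


_CHAIN_POOL = ascii_uppercase + ascii_lowercase + digits


def build_superimposed_complex(
    query: Complex, template: Complex, tf: Transform
) -> Complex:
    """Template DNA plus the rigidly transformed query protein.

    All template protein chains are removed; the whole query protein is
    transformed by the single rigid ``tf`` and appended.  Query chain
    ids colliding with retained template chains are renamed (mapping
    logged).  Non-polymer template chains are dropped.
    """
    if not template.dna_chain_ids():
        raise StructureError("template has no DNA chain")
    if not query.protein_chain_ids():
        raise StructureError("query has no protein chain")

    dna_chains = set(template.dna_chain_ids())
    atoms = [replace(a, coords=a.coords.copy())
             for a in template.atoms if a.chain_id in dna_chains]

    used = set(dna_chains)
    rename: dict[str, str] = {}
    for cid in query.protein_chain_ids():
        if cid in used:
            new = next(c for c in _CHAIN_POOL if c not in used)
            rename[cid] = new
            used.add(new)
        else:
            used.add(cid)
    if rename:
        logger.info("renamed query chains on collision: %s", rename)

    prot_chains = set(query.protein_chain_ids())
    for a in query.atoms:
        if a.chain_id not in prot_chains:
            continue
        atoms.append(
            replace(a, chain_id=rename.get(a.chain_id, a.chain_id),
                    coords=tf.apply(a.coords))
        )

    out = Complex(
        atoms,
        resolution=template.resolution,
        method=template.method,
        name=f"{query.name or 'query'}-on-{template.name or 'template'}",
    )
    # sanity: warn when the placement leaves the protein off the DNA
    from .knowledgebase import R_CUT
    from scipy.spatial.distance import cdist

    pc = out.coords(out.atoms_of_kind("protein"))
    dc = out.coords(out.atoms_of_kind("dna"))
    if len(pc) and len(dc) and cdist(pc, dc).min() > R_CUT:
        logger.warning(
            "no protein atom within %.0f A of DNA after superposition; "
            "the prediction will be uninformative", R_CUT
        )
    return out
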