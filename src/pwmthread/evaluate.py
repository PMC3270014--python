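"""Comparing predicted with annotated PWMs: Psi-score and null p-values.

The Psi-score is the mean per-position Kullback-Leibler divergence
between two equal-length PWMs,

    Psi = (1/L) sum_j sum_i q_ij ln(q_ij / p_ij),

with q the annotated and p the predicted column probabilities (natural
log).  Both matrices are floored by a small pseudocount (eps = 1e-3)
and renormalized so the divergence stays finite.  Lower is better and
Psi = 0 iff the compared columns are identical after flooring.  The KL
direction (annotated vs predicted, or symmetrized) is configurable;
the annotated-as-truth direction is the default because it penalizes
predictions that put near-zero mass on truly favored bases.

Because predicted matrices are usually shorter than annotated ones,
:func:`align_pwms` scans every offset that places the shorter matrix
fully inside the longer, on the forward and reverse-complement
orientations of the prediction, and keeps the minimal Psi.

Significance is estimated from randomized PWMs: dummy matrices of the
predicted length with columns drawn uniformly from the probability
simplex (flat Dirichlet) are aligned to the annotated PWM the same
way, and the add-one empirical p-value (1 + #{dummy <= observed}) /
(n + 1) is reported; the published procedure uses n = 100,000 dummies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwm import PWM

__all__ = ["PsiResult", "psi_score", "align_pwms", "psi_pvalue",
           "DEFAULT_EPSILON", "DEFAULT_N_DUMMY"]

DEFAULT_EPSILON = 1e-3
DEFAULT_N_DUMMY = 100_000


@dataclass
class PsiResult:
    """Best alignment of a predicted PWM against an annotated one."""

    psi: float
    offset: int
    strand: str               # "forward" | "revcomp"
    l_overlap: int
    p_value: float | None = None
    n_dummy: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "offset": self.offset,
            "strand": self.strand,
            "L_overlap": self.l_overlap,
            "p_value": self.p_value,
            "n": self.n_dummy,
            "seed": self.seed,
        }


def _floor_normalize(m: np.ndarray, eps: float) -> np.ndarray:
    m = np.maximum(np.asarray(m, dtype=float), eps)
    return m / m.sum(axis=1, keepdims=True)


def psi_score(pred: PWM | np.ndarray, ann: PWM | np.ndarray,
              eps: float = DEFAULT_EPSILON,
              direction: str = "ann||pred") -> float:
    """Mean per-position KL divergence between equal-length PWMs."""
    p = pred.matrix if isinstance(pred, PWM) else np.asarray(pred, float)
    q = ann.matrix if isinstance(ann, PWM) else np.asarray(ann, float)
    if p.shape != q.shape:
        raise ValueError(
            f"length mismatch ({p.shape[0]} vs {q.shape[0]}); align first"
        )
    p = _floor_normalize(p, eps)
    q = _floor_normalize(q, eps)
    if direction == "ann||pred":
        kl = q * (np.log(q) - np.log(p))
    elif direction == "pred||ann":
        kl = p * (np.log(p) - np.log(q))
    elif direction == "symmetric":
        kl = 0.5 * (q * (np.log(q) - np.log(p)) + p * (np.log(p) - np.log(q)))
    else:
        raise ValueError(f"unknown KL direction {direction!r}")
    return float(kl.sum() / p.shape[0])


def _placements(short_len: int, long_len: int):
    for offset in range(long_len - short_len + 1):
        yield offset


def align_pwms(pred: PWM, ann: PWM, eps: float = DEFAULT_EPSILON,
               direction: str = "ann||pred") -> PsiResult:
    """Minimal Psi over all placements of the shorter PWM in the longer.

    Both forward and reverse-complement orientations of the predicted
    matrix are scanned; ties prefer the smaller offset and the forward
    strand.  ``offset`` is the start of the shorter matrix within the
    longer one.
    """
    if len(pred) == 0 or len(ann) == 0:
        raise ValueError("both PWMs must be non-empty")
    pred_shorter = len(pred) <= len(ann)
    short, long_ = (pred, ann) if pred_shorter else (ann, pred)
    lo = len(long_)
    ls = len(short)
    best: PsiResult | None = None
    for strand, oriented_pred in (("forward", pred), ("revcomp",
                                                      pred.reverse_complement())):
        short_m = oriented_pred.matrix if pred_shorter else short.matrix
        long_m = long_.matrix if pred_shorter else oriented_pred.matrix
        for offset in _placements(ls, lo):
            window = long_m[offset:offset + ls]
            if pred_shorter:
                psi = psi_score(short_m, window, eps=eps, direction=direction)
            else:
                psi = psi_score(window, short.matrix, eps=eps,
                                direction=direction)
            if best is None or psi < best.psi - 1e-15:
                best = PsiResult(psi=psi, offset=offset, strand=strand,
                                 l_overlap=ls)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# randomized-PWM null
# ---------------------------------------------------------------------------

def _null_psis(ann: PWM, length: int, n: int, rng: np.random.Generator,
               eps: float, direction: str) -> np.ndarray:
    """Aligned Psi of n flat-Dirichlet dummy PWMs, vectorized."""
    if length > len(ann):
        raise ValueError("dummy length exceeds annotated PWM length")
    # columns uniform on the 3-simplex: normalized Exponential(1) draws
    raw = rng.standard_exponential(size=(n, length, 4))
    dummies = raw / raw.sum(axis=2, keepdims=True)
    p = np.maximum(dummies, eps)
    p /= p.sum(axis=2, keepdims=True)
    logp = np.log(p)
    q_full = _floor_normalize(ann.matrix, eps)
    logq_full = np.log(q_full)

    n_off = len(ann) - length + 1
    best = np.full(n, np.inf)
    for flip in (False, True):
        # reverse-complementing the dummy equals scanning its columns
        # reversed with bases swapped
        pp = p[:, ::-1, ::-1] if flip else p
        lpp = logp[:, ::-1, ::-1] if flip else logp
        for o in range(n_off):
            q = q_full[o:o + length]
            lq = logq_full[o:o + length]
            if direction == "ann||pred":
                kl = (q * lq).sum() - np.einsum("lk,nlk->n", q, lpp)
            elif direction == "pred||ann":
                kl = np.einsum("nlk,nlk->n", pp, lpp) - \
                    np.einsum("nlk,lk->n", pp, lq)
            else:
                kl = 0.5 * (
                    (q * lq).sum() - np.einsum("lk,nlk->n", q, lpp)
                    + np.einsum("nlk,nlk->n", pp, lpp)
                    - np.einsum("nlk,lk->n", pp, lq)
                )
            np.minimum(best, kl / length, out=best)
    return best


def psi_pvalue(pred_psi: float, ann: PWM, length: int,
               n: int = DEFAULT_N_DUMMY, seed: int | None = None,
               eps: float = DEFAULT_EPSILON,
               direction: str = "ann||pred") -> float:
    """Empirical add-one p-value of a Psi-score under the dummy null.

    Generates ``n`` dummy PWMs of the given length (flat-Dirichlet
    columns), aligns each to the annotated PWM exactly as a prediction
    would be, and returns (1 + #{Psi_dummy <= pred_psi}) / (n + 1).
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    null = _null_psis(ann, length, n, rng, eps, direction)
    return float((1 + int((null <= pred_psi).sum())) / (n + 1))
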