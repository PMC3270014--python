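"""The all-atom knowledge-based pair potential and complex scoring.

The potential follows the inverse-Boltzmann construction of the FIRE
family of protein-DNA scoring functions:

    u(i, j, r) = -ln[ P(i, j, r) / P_ref(r) ]          for r <= r_cut
    u(i, j, r) = 0                                     beyond r_cut

with the observed distance distribution P(i, j, r) estimated from
knowledgebase counts N_obs(i, j, r) and the reference state

    P_ref(r) = r^alpha * dr(r) / sum_r' r'^alpha * dr(r')

using alpha = 1.61.  An optional distance-dependent weighting scheme
w(r) = (r / r_cut)^gamma re-emphasizes long-range contacts before the
observed distribution is normalized; the default is no weighting (the
plain FIRE form).  A per-bin pseudocount delta keeps the log finite
for informative type pairs with empty bins; type pairs never observed
at any distance contribute zero energy.

The binding free energy of a complex is the sum of u over every
protein-DNA heavy-atom pair within r_cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .atomtypes import N_DNA_TYPES, N_PROTEIN_TYPES
from .knowledgebase import (
    BIN_UPPER_EDGES,
    BIN_WIDTHS,
    N_BINS,
    Knowledgebase,
    _bin_indices,
    _typed_arrays,
    bin_index,
)
from .structio import Complex

__all__ = [
    "PotentialParams",
    "PairPotential",
    "reference_probability",
    "observed_probability",
    "pair_potential",
    "derive_potential",
    "binding_free_energy",
]

logger = logging.getLogger(__name__)

_EDGES = np.array(BIN_UPPER_EDGES, dtype=float)
_WIDTHS = np.array(BIN_WIDTHS, dtype=float)


@dataclass(frozen=True)
class PotentialParams:
    """Tunable parameters of the potential and of PWM emission.

    alpha : exponent of the r^alpha reference state (1.61).
    r_cut : interaction cutoff, fixed at the last bin edge (10 A).
    pseudocount : additive per-bin count delta; 0 disables smoothing.
    weighting : "none" for plain FIRE, or "power:<gamma>" for
        w(r) = (r/r_cut)^gamma applied to bin counts before
        normalization.
    beta : temperature-like divisor converting threading energies to
        PWM column probabilities (15).
    """

    alpha: float = 1.61
    r_cut: float = 10.0
    pseudocount: float = 0.1
    weighting: str = "none"
    beta: float = 15.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.r_cut != BIN_UPPER_EDGES[-1]:
            raise ValueError("r_cut must equal the last bin edge (10 A)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        self._weight_vector()  # validates the scheme id

    def _weight_vector(self) -> np.ndarray:
        if self.weighting == "none":
            return np.ones(N_BINS)
        if self.weighting.startswith("power:"):
            gamma = float(self.weighting.split(":", 1)[1])
            return (_EDGES / self.r_cut) ** gamma
        raise ValueError(f"unknown weighting scheme {self.weighting!r}")


def reference_probability(r: int, params: PotentialParams) -> float:
    """P_ref(r) = r^alpha dr / sum r'^alpha dr' for bin label r."""
    b = bin_index(r)
    w = _EDGES ** params.alpha * _WIDTHS
    return float(w[b] / w.sum())


def _reference_vector(params: PotentialParams) -> np.ndarray:
    w = _EDGES ** params.alpha * _WIDTHS
    return w / w.sum()


def observed_probability(
    kb: Knowledgebase, i: int, j: int, r: int, params: PotentialParams
) -> float:
    """Normalized (optionally weighted, pseudocounted) observed P(i,j,r)."""
    c = kb.counts[i, j].astype(float) + params.pseudocount
    c = c * params._weight_vector()
    tot = c.sum()
    if tot == 0:
        raise ValueError(f"type pair ({i},{j}) has no counts and no pseudocount")
    return float(c[bin_index(r)] / tot)


@dataclass
class PairPotential:
    """The derived energy table u(i, j, r) with its parameters."""

    u: np.ndarray
    params: PotentialParams
    source: str = ""
    informative: np.ndarray = field(
        default_factory=lambda: np.zeros((N_PROTEIN_TYPES, N_DNA_TYPES), bool)
    )

    def energy(self, i: int, j: int, r: int) -> float:
        return float(self.u[i, j, bin_index(r)])


def derive_potential(kb: Knowledgebase, params: PotentialParams | None = None,
                     ) -> PairPotential:
    """Turn knowledgebase counts into the energy table u = -ln(P/P_ref).

    Type pairs with zero total raw count are uninformative and get
    u = 0 in every bin regardless of pseudocount.
    """
    params = params or PotentialParams()
    counts = kb.counts.astype(float)
    informative = counts.sum(axis=2) > 0
    c = counts + params.pseudocount
    c = c * params._weight_vector()[None, None, :]
    tot = c.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, c / np.where(tot > 0, tot, 1.0), 0.0)
        ratio = p / _reference_vector(params)[None, None, :]
        u = -np.log(np.where(ratio > 0, ratio, 1.0))
        u[ratio <= 0] = np.inf
    u[~informative] = 0.0
    if params.pseudocount > 0 and not np.all(np.isfinite(u)):
        raise AssertionError("pseudocount should guarantee finite energies")
    u[~np.isfinite(u)] = 0.0  # delta=0: empty bins of informative pairs
    return PairPotential(u=u, params=params, source=kb.provenance,
                         informative=informative)


def pair_potential(kb: Knowledgebase, i: int, j: int, r: int,
                   params: PotentialParams | None = None) -> float:
    """u(i, j, r) computed directly from knowledgebase counts."""
    params = params or PotentialParams()
    if not kb.counts[i, j].sum() > 0:
        return 0.0
    p = observed_probability(kb, i, j, r, params)
    return float(-np.log(p / reference_probability(r, params)))


def _pairwise_energy(pot: PairPotential, pc, pi, dc, di) -> float:
    if len(pc) == 0 or len(dc) == 0:
        return 0.0
    d = cdist(pc, dc)
    bins = _bin_indices(d)
    ii, jj = np.nonzero(bins >= 0)
    if len(ii) == 0:
        return 0.0
    return float(pot.u[pi[ii], di[jj], bins[ii, jj]].sum())


def binding_free_energy(cx: Complex, pot: PairPotential) -> float:
    """Sum of pair potentials over all protein-DNA contacts within r_cut."""
    pc, pi, _ = _typed_arrays(cx, "protein")
    dc, di, _ = _typed_arrays(cx, "dna")
    return _pairwise_energy(pot, pc, pi, dc, di)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def save_potential(pot: PairPotential, path_or_file) -> None:
    """Export the nonzero energy table as TSV with a parameter header."""
    from .atomtypes import DNA_TYPES, PROTEIN_TYPES

    lines = [f"#params\t{pot.params!r}", f"#source\t{pot.source}"]
    nz = np.nonzero(pot.u)
    for i, j, b in zip(*nz):
        lines.append(
            f"{PROTEIN_TYPES[i]}\t{DNA_TYPES[j]}\t{BIN_UPPER_EDGES[b]}\t"
            f"{pot.u[i, j, b]:.9g}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        with open(path_or_file, "w") as fh:
            fh.write(text)
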