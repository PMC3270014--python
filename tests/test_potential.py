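"""Reference state, observed probabilities and the pair potential."""

import numpy as np
import pytest

from pwmthread import (
    Knowledgebase,
    PotentialParams,
    binding_free_energy,
    derive_potential,
    observed_probability,
    pair_potential,
    reference_probability,
)
from pwmthread.knowledgebase import BIN_UPPER_EDGES, BIN_WIDTHS
from pwmthread.structio import Atom, Complex

from conftest import random_rigid_transform
from pwmthread.superpose import apply_transform


class TestReferenceState:
    @pytest.mark.parametrize("alpha", [0.0, 1.61, 3.0])
    def test_normalization(self, alpha):
        p = PotentialParams(alpha=alpha)
        total = sum(reference_probability(r, p) for r in BIN_UPPER_EDGES)
        assert abs(total - 1.0) < 1e-12

    def test_alpha_zero_is_width_weighted(self):
        p = PotentialParams(alpha=0.0)
        assert reference_probability(3, p) == pytest.approx(0.3, abs=1e-15)
        for r in BIN_UPPER_EDGES[1:]:
            assert reference_probability(r, p) == pytest.approx(0.1, abs=1e-15)

    def test_volume_term_shifts_mass_outward(self):
        p = PotentialParams(alpha=1.61)
        probs = [reference_probability(r, p) for r in BIN_UPPER_EDGES]
        assert all(np.diff(probs[1:]) > 0)   # grows with r beyond the wide bin


def _kb_with_counts(i, j, counts):
    kb = Knowledgebase()
    kb.counts[i, j, :] = counts
    return kb


class TestObservedProbability:
    def test_single_occupied_bin(self):
        kb = _kb_with_counts(0, 0, [0, 0, 0, 0, 0, 0, 0, 8])
        p = PotentialParams(pseudocount=0.0)
        assert observed_probability(kb, 0, 0, 10, p) == 1.0

    def test_uniform_counts(self):
        kb = _kb_with_counts(0, 0, [1] * 8)
        p = PotentialParams(pseudocount=0.0)
        for r in BIN_UPPER_EDGES:
            assert observed_probability(kb, 0, 0, r, p) == pytest.approx(1 / 8)

    def test_power_weighting_rescales_bins(self):
        kb = _kb_with_counts(0, 0, [1] * 8)
        p = PotentialParams(pseudocount=0.0, weighting="power:1")
        ratio = observed_probability(kb, 0, 0, 10, p) / \
            observed_probability(kb, 0, 0, 3, p)
        assert ratio == pytest.approx(10 / 3, rel=1e-12)

    def test_normalized_for_every_informative_pair(self):
        rng = np.random.default_rng(0)
        kb = _kb_with_counts(5, 7, rng.integers(0, 50, size=8))
        for params in (PotentialParams(), PotentialParams(weighting="power:1")):
            total = sum(observed_probability(kb, 5, 7, r, params)
                        for r in BIN_UPPER_EDGES)
            assert total == pytest.approx(1.0, abs=1e-12)


class TestPairPotential:
    def test_zero_when_observed_matches_reference(self):
        # at alpha=0 the reference is exactly the bin widths /10,
        # realizable with integer counts (3,1,1,...,1)
        kb = _kb_with_counts(0, 0, list(BIN_WIDTHS))
        p = PotentialParams(alpha=0.0, pseudocount=0.0)
        for r in BIN_UPPER_EDGES:
            assert pair_potential(kb, 0, 0, r, p) == pytest.approx(0.0, abs=1e-12)

    def test_minus_one_when_e_fold_enriched(self):
        # construct P(4) = e * P_ref(4) at alpha=0 (P_ref(4) = 0.1):
        # c4 = e*K and the remaining (10-e)*K spread over the other bins
        K = 10_000_000
        counts = np.zeros(8, dtype=np.int64)
        counts[1] = round(np.e * K)
        rest = 10 * K - counts[1]
        counts[[0, 2, 3, 4, 5, 6, 7]] = rest // 7
        counts[0] += rest - 7 * (rest // 7)
        kb = _kb_with_counts(0, 0, counts)
        p = PotentialParams(alpha=0.0, pseudocount=0.0)
        assert pair_potential(kb, 0, 0, 4, p) == pytest.approx(-1.0, abs=1e-6)

    def test_uninformative_pair_is_zero(self):
        kb = Knowledgebase()
        kb.counts[1, 1, :] = [0, 5, 0, 0, 0, 0, 0, 0]
        pot = derive_potential(kb, PotentialParams())
        assert np.all(pot.u[0, 0, :] == 0.0)        # no counts anywhere
        assert np.any(pot.u[1, 1, :] != 0.0)

    def test_enrichment_monotonicity(self):
        rng = np.random.default_rng(7)
        params = PotentialParams()
        for _ in range(20):
            counts = rng.integers(0, 30, size=8)
            counts[counts.argmin()] += 1  # ensure informative
            kb = _kb_with_counts(3, 4, counts)
            r = int(rng.choice(BIN_UPPER_EDGES))
            u0 = pair_potential(kb, 3, 4, r, params)
            counts2 = counts.copy()
            counts2[list(BIN_UPPER_EDGES).index(r)] += 5
            kb2 = _kb_with_counts(3, 4, counts2)
            u1 = pair_potential(kb2, 3, 4, r, params)
            assert u1 < u0

    def test_derive_matches_elementwise_formula(self, planted_potential):
        _, kb, pot = planted_potential
        rng = np.random.default_rng(1)
        informative = np.argwhere(pot.informative)
        for i, j in informative[rng.choice(len(informative), 25)]:
            for r in BIN_UPPER_EDGES:
                assert pot.u[i, j, BIN_UPPER_EDGES.index(r)] == pytest.approx(
                    pair_potential(kb, i, j, r, pot.params), abs=1e-12
                )


class TestBindingFreeEnergy:
    def test_empty_when_no_pairs_in_range(self, planted_potential):
        _, _, pot = planted_potential
        atoms = [
            Atom("A", "ALA", 1, "CA", "C", np.zeros(3)),
            Atom("B", "DG", 1, "N7", "N", np.array([15.0, 0.0, 0.0])),
        ]
        assert binding_free_energy(Complex(atoms), pot) == 0.0

    def test_two_pair_sum_matches_table_lookups(self, planted_potential):
        _, _, pot = planted_potential
        from pwmthread.atomtypes import DNA_INDEX, PROTEIN_INDEX

        atoms = [
            Atom("A", "ALA", 1, "CA", "C", np.zeros(3)),
            Atom("B", "DG", 1, "N7", "N", np.array([3.5, 0.0, 0.0])),
            Atom("B", "DG", 1, "O6", "O", np.array([0.0, 7.2, 0.0])),
        ]
        expected = pot.energy(PROTEIN_INDEX["ALA.CA"], DNA_INDEX["DG.N7"], 4) \
            + pot.energy(PROTEIN_INDEX["ALA.CA"], DNA_INDEX["DG.O6"], 8)
        assert binding_free_energy(Complex(atoms), pot) == \
            pytest.approx(expected, abs=1e-12)

    def test_rigid_invariance(self, planted_potential, held_out_g):
        _, _, pot = planted_potential
        cx, _ = held_out_g
        rng = np.random.default_rng(99)
        dg0 = binding_free_energy(cx, pot)
        for _ in range(5):
            tf = random_rigid_transform(rng)
            assert abs(binding_free_energy(apply_transform(cx, tf), pot)
                       - dg0) < 1e-9

    def test_additive_over_distant_subcomplexes(self, planted_potential):
        _, _, pot = planted_potential
        from pwmthread import FixtureSpec, make_toy_complex

        spec = FixtureSpec(dna_sequence="GATTACCA", protein_size=45,
                           planted_contacts=(("ARG.NH1", "DG.O6", 3.5, 0),),
                           seed=5)
        cx = make_toy_complex(spec)
        shifted = cx.copy()
        for a in shifted.atoms:
            a.chain_id = {"A": "D", "B": "E", "C": "F"}[a.chain_id]
            a.coords = a.coords + np.array([200.0, 0.0, 0.0])
        merged = Complex(cx.atoms + shifted.atoms)
        assert binding_free_energy(merged, pot) == pytest.approx(
            2 * binding_free_energy(cx, pot), abs=1e-9
        )
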