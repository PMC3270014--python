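"""Base-pair substitution, per-position energies and PWM emission."""

import numpy as np
import pytest

from pwmthread import (
    PairPotential,
    PotentialParams,
    detect_duplex,
    make_bdna,
    position_energies,
    predict_pwm,
    substitute_base_pair,
)
from pwmthread.baselib import BASE_COORDS, COMPLEMENT, RESNAME
from pwmthread.structio import Atom, Complex, StructureError
from pwmthread.threader import _BACKBONE_NAMES, boltzmann_column

from conftest import random_rigid_transform
from pwmthread.superpose import apply_transform


def _backbone_coords(cx, key):
    return {a.atom_name: a.coords.copy() for a in cx.atoms
            if a.residue_key == key and a.atom_name in _BACKBONE_NAMES}


class TestSubstituteBasePair:
    def test_backbone_bitwise_unchanged(self, bdna8):
        duplex = detect_duplex(bdna8)
        ref_key, partner_key = duplex.pairs[3]
        before_ref = _backbone_coords(bdna8, ref_key)
        before_par = _backbone_coords(bdna8, partner_key)
        sub = substitute_base_pair(bdna8, duplex, 3, "G")
        for key, before in ((ref_key, before_ref), (partner_key, before_par)):
            after = _backbone_coords(sub, key)
            assert set(after) == set(before)
            for name in before:
                assert np.array_equal(after[name], before[name])

    def test_partner_becomes_complement(self, bdna8):
        duplex = detect_duplex(bdna8)
        for base in "ACGT":
            sub = substitute_base_pair(bdna8, duplex, 2, base)
            ref_key, partner_key = duplex.pairs[2]
            ref_res = next(a for a in sub.atoms if a.residue_key == ref_key)
            par_res = next(a for a in sub.atoms if a.residue_key == partner_key)
            assert ref_res.residue_name == RESNAME[base]
            assert par_res.residue_name == RESNAME[COMPLEMENT[base]]

    def test_self_substitution_idempotent(self, bdna8):
        duplex = detect_duplex(bdna8)
        base = duplex.reference_sequence[4]
        s1 = substitute_base_pair(bdna8, duplex, 4, base)
        s2 = substitute_base_pair(s1, duplex, 4, base)
        keys = set(duplex.pairs[4])
        a1 = [a for a in s1.atoms if a.residue_key in keys]
        a2 = [a for a in s2.atoms if a.residue_key in keys]
        assert [a.atom_name for a in a1] == [a.atom_name for a in a2]
        err = max(float(np.abs(x.coords - y.coords).max())
                  for x, y in zip(a1, a2))
        assert err < 1e-9

    def test_glycosidic_bond_matches_library(self, bdna8):
        duplex = detect_duplex(bdna8)
        ref_key, _ = duplex.pairs[0]
        sub = substitute_base_pair(bdna8, duplex, 0, "A")  # G -> A
        res = {a.atom_name: a.coords for a in sub.atoms
               if a.residue_key == ref_key}
        got = float(np.linalg.norm(res["C1'"] - res["N9"]))
        lib = float(np.linalg.norm(BASE_COORDS["A"]["C1'"]
                                   - BASE_COORDS["A"]["N9"]))
        assert abs(got - lib) < 0.05

    def test_base_ring_planarity(self, bdna8):
        duplex = detect_duplex(bdna8)
        sub = substitute_base_pair(bdna8, duplex, 5, "T")
        ref_key, _ = duplex.pairs[5]
        ring = [a.coords for a in sub.atoms if a.residue_key == ref_key
                and a.atom_name in ("N1", "C2", "N3", "C4", "C5", "C6")]
        pts = np.array(ring) - np.mean(ring, axis=0)
        sv = np.linalg.svd(pts, compute_uv=False)
        assert sv[-1] < 0.05

    def test_unpaired_position_rejected(self, bdna8):
        duplex = detect_duplex(bdna8)
        with pytest.raises(StructureError):
            substitute_base_pair(bdna8, duplex, 8, "A")

    def test_input_not_mutated(self, bdna8):
        before = bdna8.coords().copy()
        duplex = detect_duplex(bdna8)
        substitute_base_pair(bdna8, duplex, 0, "T")
        assert np.array_equal(bdna8.coords(), before)


def _single_entry_potential(ptype, dtype, value, bins=None):
    """Potential table nonzero only for one (protein, DNA) type pair."""
    from pwmthread.atomtypes import (DNA_INDEX, N_DNA_TYPES,
                                     N_PROTEIN_TYPES, PROTEIN_INDEX)
    from pwmthread.knowledgebase import N_BINS

    u = np.zeros((N_PROTEIN_TYPES, N_DNA_TYPES, N_BINS))
    sel = slice(None) if bins is None else bins
    u[PROTEIN_INDEX[ptype], DNA_INDEX[dtype], sel] = value
    return PairPotential(u=u, params=PotentialParams())


class TestPositionEnergies:
    def test_uncontacted_position_uniform(self, bdna8):
        # protein atom far from everything
        atoms = bdna8.atoms + [
            Atom("A", "ALA", 1, "CA", "C", np.array([100.0, 0.0, 0.0]))
        ]
        cx = Complex(atoms)
        duplex = detect_duplex(cx)
        pot = _single_entry_potential("ALA.CA", "DG.O6", -1.0)
        pe = position_energies(cx, duplex, 3, pot)
        assert not pe.contacted
        assert len(set(pe.energies.values())) == 1

    def test_single_lookup_construction(self, bdna8):
        duplex = detect_duplex(bdna8)
        target = next(a for a in bdna8.atoms
                      if a.chain_id == "B" and a.residue_number == 1
                      and a.atom_name == "O6")
        probe = target.coords + np.array([2.8, 0.0, 0.0])
        cx = Complex(bdna8.atoms + [Atom("A", "ALA", 1, "CA", "C", probe)])
        duplex = detect_duplex(cx)
        # restrict the table to the innermost bin so only the planted
        # 2.8 A contact can score; threading C puts a guanine O6 on the
        # partner strand, but several Angstroms away
        pot = _single_entry_potential("ALA.CA", "DG.O6", -2.5, bins=0)
        pe = position_energies(cx, duplex, 0, pot)
        assert pe.contacted
        assert pe.energies["G"] == pytest.approx(-2.5)
        assert pe.energies["A"] == 0.0
        assert pe.energies["C"] == 0.0
        # threading T places adenine on the partner strand, not guanine
        assert pe.energies["T"] == 0.0

    def test_rigid_invariance(self, planted_potential, held_out_g):
        _, _, pot = planted_potential
        cx, duplex = held_out_g
        rng = np.random.default_rng(17)
        base_pe = position_energies(cx, duplex, 6, pot)
        for _ in range(5):
            tf = random_rigid_transform(rng)
            moved = apply_transform(cx, tf)
            pe = position_energies(moved, duplex, 6, pot)
            for b in "ACGT":
                assert abs(pe.energies[b] - base_pe.energies[b]) < 1e-9


class TestBoltzmannColumn:
    def test_equal_energies_uniform(self):
        col = boltzmann_column(np.array([2.0, 2.0, 2.0, 2.0]), beta=15.0)
        assert np.allclose(col, 0.25, atol=1e-15)

    def test_ratio_three(self):
        beta = 15.0
        col = boltzmann_column(
            np.array([0.0, beta * np.log(3), 1e6, 1e6]), beta=beta
        )
        assert col[0] / col[1] == pytest.approx(3.0, rel=1e-12)

    def test_high_temperature_limit(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(-50, 50, size=4)
        col = boltzmann_column(e, beta=1e6)
        assert np.abs(col - 0.25).sum() / 2 < 1e-3   # total variation

    def test_low_temperature_concentrates_on_argmin(self):
        e = np.array([-3.0, 1.0, 0.0, 2.0])
        col = boltzmann_column(e, beta=1e-3)
        assert col[0] > 1 - 1e-9

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        e = rng.uniform(-5, 5, size=4)
        c1 = boltzmann_column(e, beta=15.0)
        c2 = boltzmann_column(e + 123.456, beta=15.0)
        assert np.abs(c1 - c2).max() < 1e-12

    def test_monotone_energy_probability_relation(self):
        rng = np.random.default_rng(5)
        e = rng.uniform(-5, 5, size=4)
        col = boltzmann_column(e, beta=15.0)
        order_e = np.argsort(e)
        order_p = np.argsort(-col)
        assert np.array_equal(order_e, order_p)


class TestPredictPwm:
    def test_columns_stochastic_and_flagged(self, planted_potential,
                                            held_out_g):
        _, _, pot = planted_potential
        cx, duplex = held_out_g
        pwm, details = predict_pwm(cx, duplex, pot)
        assert len(pwm) == duplex.n_paired
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)
        for pe, flag in zip(details, pwm.contacted):
            assert pe.contacted == flag
            if not flag:
                assert np.allclose(
                    pwm.matrix[pe.position], 0.25, atol=1e-12
                )

    def test_recovers_planted_preference(self, planted_potential,
                                         held_out_g):
        _, _, pot = planted_potential
        cx, duplex = held_out_g
        pwm, _ = predict_pwm(cx, duplex, pot)
        center = len(duplex.pairs) // 2
        assert pwm.consensus()[center] == "G"
        assert pwm.matrix[center, 2] > 0.5

    def test_independent_of_template_sequence(self, planted_potential,
                                              held_out_g):
        """Threading rebuilds each position, so the DNA sequence present
        in the template cannot influence the emitted PWM."""
        _, _, pot = planted_potential
        cx, duplex = held_out_g
        pwm0, _ = predict_pwm(cx, duplex, pot)
        mutated = cx
        for i in range(len(duplex.pairs)):
            mutated = substitute_base_pair(mutated, duplex, i, "ACGT"[i % 4])
        pwm1, _ = predict_pwm(mutated, detect_duplex(mutated), pot)
        assert np.allclose(pwm0.matrix, pwm1.matrix, atol=1e-9)

    def test_trim_to_contacts(self, planted_potential, held_out_g):
        _, _, pot = planted_potential
        cx, duplex = held_out_g
        full, _ = predict_pwm(cx, duplex, pot)
        trimmed, _ = predict_pwm(cx, duplex, pot, trim_to_contacts=True)
        idx = np.nonzero(full.contacted)[0]
        assert len(trimmed) == idx[-1] - idx[0] + 1
        assert np.array_equal(trimmed.matrix,
                              full.matrix[idx[0]:idx[-1] + 1])
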