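import pytest

from pwmthread import (
    FixtureSpec,
    build_knowledgebase,
    derive_potential,
    detect_duplex,
    make_planted_kb_corpus,
    make_toy_complex,
)

PDB_3_ATOMS = """\
HEADER    TOY
EXPDTA    X-RAY DIFFRACTION
REMARK   2 RESOLUTION.    2.00 ANGSTROMS.
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.729   5.245  -4.243  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def bdna8():
    from pwmthread import make_bdna

    return make_bdna("GATTACCA")


@pytest.fixture(scope="session")
def toy_complex():
    """45-residue protein + 8-bp duplex with six planted contacts.

    Built to clear every knowledgebase admission criterion.
    """
    contacts = [("ARG.NH1", "DG.O6", 3.5, 0)]
    contacts += [("ALA.CB", "DA.OP1", 4.3, 1), ("ALA.CB", "DT.OP1", 4.3, 2),
                 ("ALA.CB", "DT.OP1", 4.3, 3), ("ALA.CB", "DA.OP1", 4.3, 4),
                 ("ALA.CB", "DC.OP1", 4.3, 5)]
    spec = FixtureSpec(dna_sequence="GATTACCA", protein_size=45,
                       planted_contacts=tuple(contacts), seed=7)
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def planted_potential():
    """(corpus, knowledgebase, potential) for a planted G preference."""
    corpus = make_planted_kb_corpus(20, "G", seed=11)
    kb = build_knowledgebase(corpus)
    return corpus, kb, derive_potential(kb)


@pytest.fixture(scope="session")
def held_out_g():
    cx = make_planted_kb_corpus(1, "G", seed=1234)[0]
    return cx, detect_duplex(cx)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from pwmthread import Transform

    U = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return Transform(U, t)
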