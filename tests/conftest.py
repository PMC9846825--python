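"""Shared fixtures: the worked-example peptides and a small synthetic proteome."""

import pytest

from opxl import (
    DEP,
    EK_ISOPEPTIDE,
    MOX,
    CrossLinkCandidate,
    DigestSpec,
    ModifiedPeptide,
    digest,
)

# Tubulin alpha 1A peptide carrying diethyl phosphate on E9 (protein E411)
# and oxidized methionine at position 11.
TUBULIN_DEP_E_SEQ = "AFVHWYVGEGMEEGEFSEAR"

# The identified cross-linked pair: tubulin alpha 1A (E55 within TIGGG...)
# by MAP2 (K1635 within STKSPR), joined by the -H2O isopeptide bridge.
XL_A_SEQ = "TIGGGDDSFNTFFSETGA"
XL_B_SEQ = "STKSPR"


@pytest.fixture
def dep_e_peptide() -> ModifiedPeptide:
    return ModifiedPeptide(TUBULIN_DEP_E_SEQ).with_mod(9, DEP).with_mod(11, MOX)


@pytest.fixture
def xl_pair() -> CrossLinkCandidate:
    return CrossLinkCandidate(
        ModifiedPeptide(XL_A_SEQ), 15, ModifiedPeptide(XL_B_SEQ), 3, EK_ISOPEPTIDE
    )


# Synthetic proteins assembled from tryptic units (every unit ends in K/R,
# none contains C or P) so a full-specificity digest recovers the units.
SYNTH_PROTEINS = [
    ("synt_prot1", "TIGGGDDSFNTFFSETGAK" + "STKSPR" + "LNDLEEALQQAK" + "GFEAVTK"),
    (
        "synt_prot2",
        "DSLSQQLNSK" + "YVPSSTR" + "EILDMAR" + "TPSGFNK" + "AVLMSEK" + "WQNDPTR",
    ),
]

FULL_DIGEST = DigestSpec("full", 0, 4, 40)


@pytest.fixture(scope="session")
def synth_proteins():
    return SYNTH_PROTEINS


@pytest.fixture(scope="session")
def synth_pool() -> list[str]:
    return sorted(
        {
            p.sequence
            for pid, seq in SYNTH_PROTEINS
            for p in digest(seq, FULL_DIGEST, protein_id=pid)
        }
    )


@pytest.fixture
def synth_fasta(tmp_path, synth_proteins):
    path = tmp_path / "proteins.fasta"
    with open(path, "w") as fh:
        for pid, seq in synth_proteins:
            fh.write(f">{pid}\n{seq}\n")
    return path
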