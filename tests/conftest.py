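import numpy as np
import pytest

from tsrkit.reference import MatureTRNA, TRNAGeneRecord, build_mature_trna
from tsrkit.simulate import SimulationConfig, reference_bundle

#: worked-example fragment: a tRF-3 spanning positions 58-75 of a 75-nt
#: mature Ala tRNA, ending in the CCA tail.
ALA_FRAGMENT = "TCCCCGGCATCTCCACCA"


def _ala_gene(gene_id: str, prefix57: str) -> TRNAGeneRecord:
    """72-nt spliced Ala-CGC gene whose mature 58-75 region is ALA_FRAGMENT.

    The mature transcript is prefix57 + 'TCCCCGGCATCTCCA' + 'CCA' (75 nt);
    the prefix places the CGC anticodon at spliced position 34.
    """
    assert len(prefix57) == 57 and prefix57[33:36] == "CGC"
    spliced = prefix57 + ALA_FRAGMENT[:15]
    return TRNAGeneRecord(
        gene_id=gene_id, amino_acid="Ala", anticodon="CGC",
        chrom="chrT", start=1000, end=1000 + len(spliced) - 1, strand="+",
        genomic_seq=spliced,
    )


@pytest.fixture(scope="session")
def ala_isodecoders():
    """Two Ala-CGC isodecoders sharing the worked-example 3' fragment."""
    p1 = ("AT" * 17)[:33] + "CGC" + ("TA" * 11)[:21]
    p2 = ("TA" * 17)[:33] + "CGC" + ("AT" * 11)[:21]
    genes = [_ala_gene("tRNA-Ala-CGC-1-1", p1), _ala_gene("tRNA-Ala-CGC-2-1", p2)]
    matures = [build_mature_trna(g) for g in genes]
    for m in matures:
        assert m.L == 75 and m.anticodon_start == 34 and m.anticodon_loop == (32, 38)
        assert m.seq[57:75] == ALA_FRAGMENT
    return genes, matures


@pytest.fixture
def toy_mature():
    """Hand-specified 76-nt mature tRNA with anticodon loop at 32-38."""
    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), size=73)) + "CCA"
    return MatureTRNA(gene_id="tRNA-Gly-GCC-1-1", seq=seq,
                      anticodon_start=34, anticodon_loop=(32, 38))


@pytest.fixture(scope="session")
def small_bundle():
    """Five-gene synthetic reference used across modules."""
    return reference_bundle(SimulationConfig(seed=7, n_trnas=5, n_noise_reads=0))
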