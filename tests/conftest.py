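import numpy as np
import pytest

from proteoforge.sequence_core import Gene, GenomeAnnotation, Transcript


@pytest.fixture()
def two_gene_annotation():
    """Tiny hand-built annotation: a 2-exon '+' gene and a 1-exon '-' gene.

    chrA: positions 0-8 hold exon1 'ATG', intron 'CCC', exon2 'AAA';
    the '+' transcript T1 therefore codes 'ATGAAA' -> protein 'MK'.
    chrB holds the reverse complement of 'ATGGAATTC...' so the '-'
    transcript T2 codes 'ATGGAATTCAAA' -> 'MEFK'.
    """
    chrA = "ATGCCCAAATAG"
    minus_cds = "ATGGAATTCAAA"  # transcription-order CDS of T2
    from proteoforge.sequence_core import reverse_complement

    chrB = "GG" + reverse_complement(minus_cds) + "CC"
    t1 = Transcript("T1", "G1", "chrA", "+", exons=[(0, 3), (6, 9)],
                    cds=[(0, 3), (6, 9)])
    t2 = Transcript("T2", "G2", "chrB", "-", exons=[(2, 14)], cds=[(2, 14)])
    return GenomeAnnotation(
        {"chrA": chrA, "chrB": chrB},
        [Gene("G1", "chrA", "+", [t1]), Gene("G2", "chrB", "-", [t2])],
    )


@pytest.fixture(scope="session")
def synthetic_sample():
    """One fully-built synthetic sample shared by the slower tests."""
    from proteoforge.experiments import build_synthetic_sample

    truth, ssdb, refdb, proteome = build_synthetic_sample(seed=11)
    return truth, ssdb, refdb, proteome


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
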