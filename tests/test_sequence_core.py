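import numpy as np
import pytest
from Bio.Seq import Seq

from proteoforge.sequence_core import (
    GenomeAnnotation,
    ProteinEntry,
    parse_protein_header,
    read_gene_models,
    read_genome_fasta,
    read_protein_fasta,
    reverse_complement,
    spliced_cds_sequence,
    translate_nt,
    write_protein_fasta,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestGenomeFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        assert read_genome_fasta(p) == {"chr1": "ACGT"}

    def test_case_folding_and_line_joining(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgt\nACG\n")
        assert read_genome_fasta(p) == {"c1": "ACGTACG"}

    def test_duplicate_record_is_an_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n>c1\nGGGG\n")
        with pytest.raises(ValueError, match="c1"):
            read_genome_fasta(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_genome_fasta(p)


GTF_BASIC = (
    "c1\tx\texon\t11\t20\t.\t+\t.\t"
    'gene_id "g"; transcript_id "t";\n'
)


class TestGeneModels:
    def test_gtf_coordinates_become_half_open(self, tmp_path):
        p = tmp_path / "m.gtf"
        p.write_text(GTF_BASIC)
        genes = read_gene_models(p, "gtf")
        assert genes[0].transcripts[0].exons == [(10, 20)]

    def test_intron_is_the_gap_between_exons(self, tmp_path):
        p = tmp_path / "m.gtf"
        lines = [
            f'c1\tx\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g"; transcript_id "t";'
            for s, e in [(31, 40), (11, 20)]  # deliberately out of order
        ]
        p.write_text("\n".join(lines) + "\n")
        t = read_gene_models(p, "gtf")[0].transcripts[0]
        assert t.exons == [(10, 20), (30, 40)]  # sorted by start
        assert t.introns() == [(20, 30)]

    def test_mixed_strand_transcript_rejected(self, tmp_path):
        p = tmp_path / "m.gtf"
        p.write_text(
            'c1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'c1\tx\texon\t21\t30\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="mixed strands"):
            read_gene_models(p, "gtf")

    def test_cds_outside_exon_rejected(self, tmp_path):
        p = tmp_path / "m.gtf"
        p.write_text(
            'c1\tx\texon\t11\t20\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'c1\tx\tCDS\t25\t30\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="CDS"):
            read_gene_models(p, "gtf")

    def test_gtf_half_open_round_trip_is_bijective(self, rng, tmp_path):
        # a random interval written as GTF and read back keeps its
        # 1-based inclusive coordinates and its length
        for i in range(50):
            start1 = int(rng.integers(1, 10_000))
            end1 = start1 + int(rng.integers(0, 500))
            p = tmp_path / f"m{i}.gtf"
            p.write_text(
                f'c1\tx\texon\t{start1}\t{end1}\t.\t+\t.\t'
                f'gene_id "g"; transcript_id "t";\n'
            )
            (s0, e0) = read_gene_models(p, "gtf")[0].transcripts[0].exons[0]
            assert (s0 + 1, e0) == (start1, end1)
            assert e0 - s0 == end1 - start1 + 1


class TestSplicedCds:
    def test_plus_strand_concatenation(self, two_gene_annotation):
        assert spliced_cds_sequence(two_gene_annotation, "T1") == "ATGAAA"

    def test_minus_strand_reverse_complement(self, two_gene_annotation):
        assert spliced_cds_sequence(two_gene_annotation, "T2") == "ATGGAATTCAAA"

    def test_unknown_transcript(self, two_gene_annotation):
        with pytest.raises(KeyError):
            spliced_cds_sequence(two_gene_annotation, "nope")

    def test_minus_strand_matches_biopython_oracle(self, rng):
        from proteoforge.sequence_core import Gene, Transcript

        for _ in range(50):
            chrom = "".join(rng.choice(list("ACGT"), size=120))
            a, b = sorted(rng.choice(50, size=2, replace=False))
            exon1 = (int(a), int(a) + 12)
            exon2 = (60 + int(b), 60 + int(b) + 9)
            t = Transcript("t", "g", "c", "-", [exon1, exon2], [exon1, exon2])
            ann = GenomeAnnotation({"c": chrom}, [Gene("g", "c", "-", [t])])
            mine = spliced_cds_sequence(ann, "t")
            concat = chrom[exon1[0]:exon1[1]] + chrom[exon2[0]:exon2[1]]
            assert mine == str(Seq(concat).reverse_complement())


class TestTranslate:
    def test_stop_truncation(self):
        assert translate_nt("ATGGCCTAA", 0, truncate_at_stop=True) == "MA"

    def test_frame_shift_drops_partial_codon(self):
        assert translate_nt("ATGGCC", 1) == "W"

    def test_ambiguous_codon_yields_x(self):
        assert translate_nt("ATGANA") == "MX"

    def test_empty_input(self):
        assert translate_nt("") == ""

    def test_matches_biopython_in_all_frames(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 60))
            nt = "".join(rng.choice(list("ACGT"), size=n))
            for frame in (0, 1, 2):
                sub = nt[frame:]
                sub = sub[: len(sub) - len(sub) % 3]
                assert translate_nt(nt, frame) == str(Seq(sub).translate())

    def test_reverse_strand_translation_via_oracle(self, rng):
        for _ in range(100):
            nt = "".join(rng.choice(list("ACGT"), size=33))
            rc = reverse_complement(nt)
            assert translate_nt(rc) == str(Seq(nt).reverse_complement().translate())


def _random_entry(rng, i):
    origin = ["REF", "SAV", "SJ"][int(rng.integers(3))]
    seq = "".join(rng.choice(list(AA20), size=int(rng.integers(6, 40))))
    prov = {"REF": "transcript=T%d" % i,
            "SAV": "T%d;p.K4R" % i,
            "SJ": "c1:10-20:+;orient=+;frame=0;span=2-3"}[origin]
    return ProteinEntry(f"acc{i}", seq, origin, prov, description="d%d" % i)


class TestProteinFasta:
    def test_sav_header_round_trip(self, tmp_path):
        e = ProteinEntry("T123", "MKIAYIAK", "SAV", "T123;p.K45R")
        p = tmp_path / "db.fa"
        write_protein_fasta([e], p)
        assert ">sav|T123|T123;p.K45R" in p.read_text()
        (back,) = read_protein_fasta(p)
        assert back == e

    def test_decoy_header_prefix(self, tmp_path):
        e = ProteinEntry("DECOY_T1", "RKM", "DECOY", "transcript=T1",
                         source_origin="REF")
        p = tmp_path / "db.fa"
        write_protein_fasta([e], p)
        assert p.read_text().startswith(">DECOY_ref|T1|")
        (back,) = read_protein_fasta(p)
        assert back.origin == "DECOY" and back.accession == "DECOY_T1"
        assert back.source_origin == "REF"

    def test_round_trip_identity_on_random_entries(self, tmp_path, rng):
        entries = [_random_entry(rng, i) for i in range(500)]
        p = tmp_path / "db.fa"
        write_protein_fasta(entries, p)
        assert read_protein_fasta(p) == entries

    def test_non_residue_character_rejected(self, tmp_path):
        e = ProteinEntry("bad1", "MK*R", "REF")
        with pytest.raises(ValueError, match="bad1"):
            write_protein_fasta([e], tmp_path / "db.fa")

    def test_malformed_header_rejected(self):
        with pytest.raises(ValueError):
            parse_protein_header("justoneword")
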