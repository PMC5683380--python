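"""Genome/annotation data model, translation, and FASTA / gene-model I/O.

All internal coordinates are 0-based half-open; GTF/GFF3 (1-based inclusive)
and BED (0-based half-open) are converted at the I/O boundary. Minus-strand
coding sequences are reverse-complemented as one concatenated unit, never
per exon, so codons that straddle exon boundaries are handled correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from gffutils.iterators import DataIterator

log = logging.getLogger(__name__)

# Standard nuclear genetic code, TCAG-nested codon order.
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AA[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

STOP = "*"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
# 'X' marks residues from ambiguous (N-containing) codons; such peptides are
# excluded from digestion downstream because their mass is undefined.
RESIDUES_EXTENDED = AMINO_ACIDS | {"X"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ORIGIN_TAGS = {"REF": "ref", "SAV": "sav", "SJ": "sj"}
_TAG_TO_ORIGIN = {v: k for k, v in ORIGIN_TAGS.items()}


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate_nt(nt: str, frame: int = 0, truncate_at_stop: bool = False) -> str:
    """Translate a nucleotide string in the given frame (0, 1 or 2).

    Codons containing a base other than A/C/G/T yield 'X'; a trailing
    partial codon is dropped. With ``truncate_at_stop`` the returned
    protein ends just before the first stop; otherwise stops appear as '*'.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    out: list[str] = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3].upper()
        aa = CODON_TABLE.get(codon, "X")
        if aa == STOP and truncate_at_stop:
            break
        out.append(aa)
    return "".join(out)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    frame: int = 0
    complete: bool = True

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 0-based half-open."""
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes:
            yield from g.transcripts

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts():
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"unknown transcript id: {transcript_id!r}")

    def annotated_introns(self) -> set[tuple[str, int, int, str]]:
        """(chrom, start, end, strand) of every intron in the gene model."""
        out = set()
        for t in self.transcripts():
            for s, e in t.introns():
                out.add((t.chrom, s, e, t.strand))
        return out

    def validate(self) -> None:
        for t in self.transcripts():
            if t.strand not in "+-":
                raise ValueError(f"{t.transcript_id}: strand must be + or -")
            chrom_len = len(self.chromosomes[t.chrom])
            for s, e in t.exons + t.cds:
                if not (0 <= s < e <= chrom_len):
                    raise ValueError(
                        f"{t.transcript_id}: interval [{s},{e}) outside "
                        f"chromosome {t.chrom} of length {chrom_len}"
                    )
            cds = sorted(t.cds)
            for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
                if s2 < e1:
                    raise ValueError(f"{t.transcript_id}: overlapping CDS intervals")
            if t.complete and t.frame == 0 and t.cds and t.cds_length % 3:
                raise ValueError(
                    f"{t.transcript_id}: complete CDS length {t.cds_length} "
                    "is not a multiple of 3"
                )


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into {name: uppercase sequence}, order preserved."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return chroms


def write_genome_fasta(chromosomes: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _transcript_key(feature, dialect: str) -> str:
    if dialect == "gtf":
        return feature.attributes["transcript_id"][0]
    parent = feature.attributes["Parent"][0]
    return parent.split(":", 1)[-1]


def _gene_key(feature, dialect: str) -> str | None:
    if dialect == "gtf":
        vals = feature.attributes.get("gene_id")
        return vals[0] if vals else None
    return None


def read_gene_models(path: str | Path, dialect: str = "gtf") -> list[Gene]:
    """Parse GTF or GFF3 gene models into Gene/Transcript records.

    1-based inclusive file coordinates become 0-based half-open. Exons are
    grouped by transcript_id and sorted by genomic start; a transcript whose
    features sit on mixed strands, or a CDS outside every exon, is an error.
    """
    dialect = dialect.lower()
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"dialect must be 'gtf' or 'gff3', got {dialect!r}")

    transcripts: dict[str, Transcript] = {}
    cds_frames: dict[str, dict[int, int]] = {}  # tid -> {cds start: frame}
    for feat in DataIterator(str(path)):
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = _transcript_key(feat, dialect)
        gid = _gene_key(feat, dialect) or tid
        iv = (feat.start - 1, feat.end)  # GTF/GFF 1-based inclusive -> half-open
        t = transcripts.get(tid)
        if t is None:
            t = transcripts[tid] = Transcript(tid, gid, feat.seqid, feat.strand)
        if feat.strand != t.strand:
            raise ValueError(f"transcript {tid!r} has features on mixed strands")
        if feat.seqid != t.chrom:
            raise ValueError(f"transcript {tid!r} has features on multiple chromosomes")
        if feat.featuretype == "exon":
            t.exons.append(iv)
        else:
            t.cds.append(iv)
            frame = 0 if feat.frame in (".", None) else int(feat.frame)
            cds_frames.setdefault(tid, {})[iv[0]] = frame

    genes: dict[str, Gene] = {}
    for tid, t in transcripts.items():
        t.exons.sort()
        t.cds.sort()
        for cs, ce in t.cds:
            if not any(es <= cs and ce <= ee for es, ee in t.exons):
                raise ValueError(
                    f"transcript {tid!r}: CDS [{cs},{ce}) not contained in any exon"
                )
        if t.cds:
            # frame of the first CDS base in transcription order
            frames = cds_frames[tid]
            first_start = min(frames) if t.strand == "+" else max(frames)
            t.frame = frames[first_start]
        g = genes.setdefault(t.gene_id, Gene(t.gene_id, t.chrom, t.strand))
        g.transcripts.append(t)
    return list(genes.values())


def spliced_cds_sequence(annotation: GenomeAnnotation, transcript_id: str) -> str:
    """Concatenated CDS in transcription order ('-' strand: reverse-complemented
    as one unit after concatenation)."""
    t = annotation.transcript(transcript_id)
    if not t.cds:
        raise ValueError(f"transcript {transcript_id!r} has no CDS")
    chrom = annotation.chromosomes[t.chrom]
    seq = "".join(chrom[s:e] for s, e in sorted(t.cds))
    return reverse_complement(seq) if t.strand == "-" else seq


# --------------------------------------------------------------------------
# Protein entries and the search-database FASTA grammar
# --------------------------------------------------------------------------

@dataclass
class ProteinEntry:
    """One search-database record.

    Header grammar: ``>{origin-tag}|{accession}|{provenance}`` with
    origin-tag in {ref, sav, sj}; decoy headers prepend ``DECOY_`` to the
    whole header body and the in-memory accession carries the same prefix.
    """

    accession: str
    sequence: str
    origin: str  # REF | SAV | SJ | DECOY
    provenance: str = ""
    description: str = ""
    source_origin: str | None = None  # for DECOY entries: origin of the target

    def validate(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - RESIDUES_EXTENDED
        if bad:
            raise ValueError(
                f"{self.accession}: non-residue characters {sorted(bad)!r}"
            )
        if self.origin not in ("REF", "SAV", "SJ", "DECOY"):
            raise ValueError(f"{self.accession}: bad origin {self.origin!r}")
        if "|" in self.accession or "|" in self.provenance:
            raise ValueError(f"{self.accession}: '|' not allowed in header fields")
        if self.origin == "DECOY" and not self.accession.startswith("DECOY_"):
            raise ValueError(f"{self.accession}: decoy accession must start with DECOY_")

    @property
    def is_decoy(self) -> bool:
        return self.origin == "DECOY"

    def header(self) -> str:
        if self.origin == "DECOY":
            tag = ORIGIN_TAGS[self.source_origin or "REF"]
            body = f"{tag}|{self.accession[len('DECOY_'):]}|{self.provenance}"
            body = "DECOY_" + body
        else:
            body = f"{ORIGIN_TAGS[self.origin]}|{self.accession}|{self.provenance}"
        return body + (f" {self.description}" if self.description else "")


def parse_protein_header(header: str) -> ProteinEntry:
    """Parse a header line body (no '>') into an entry without its sequence."""
    body, _, desc = header.partition(" ")
    decoy = body.startswith("DECOY_")
    if decoy:
        body = body[len("DECOY_"):]
    parts = body.split("|")
    if len(parts) != 3:
        raise ValueError(f"malformed protein header: {header!r}")
    tag, acc, prov = parts
    if tag not in _TAG_TO_ORIGIN:
        raise ValueError(f"unknown origin tag {tag!r} in header {header!r}")
    if decoy:
        return ProteinEntry("DECOY_" + acc, "", "DECOY", prov, desc, _TAG_TO_ORIGIN[tag])
    return ProteinEntry(acc, "", _TAG_TO_ORIGIN[tag], prov, desc)


def write_protein_fasta(entries: Iterable[ProteinEntry], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for e in entries:
            e.validate()
            fh.write(f">{e.header()}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


def read_protein_fasta(path: str | Path) -> list[ProteinEntry]:
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        e = parse_protein_header(rec.description)
        e.sequence = str(rec.seq)
        e.validate()
        if e.accession in seen:
            raise ValueError(f"duplicate accession in FASTA: {e.accession!r}")
        seen.add(e.accession)
        entries.append(e)
    return entries
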