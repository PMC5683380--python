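"""Novel splice-junction detection and junction-polypeptide construction.

Observed junctions (TopHat-style BED12, two blocks per record) are compared
to the gene model's introns by exact intron coordinates; only junctions
absent from the model are retained. Sequence flanking each retained
junction is spliced together and translated — three frames on the known
strand, or all six when the strand is unknown — and every stop-free segment
that spans the junction with at least one residue on each side becomes an
SJ database entry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .sequence_core import (
    GenomeAnnotation,
    ProteinEntry,
    reverse_complement,
    translate_nt,
)

# provenance grammar: <chrom>:<start>-<end>:<strand>;orient=<+/->;frame=<f>;span=<jl>-<jr>
SJ_PROV_RE = re.compile(
    r"^(?P<chrom>[^:;]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+.-]);"
    r"orient=(?P<orient>[+-]);frame=(?P<frame>[012]);span=(?P<jl>\d+)-(?P<jr>\d+)$"
)


@dataclass(frozen=True)
class SpliceJunction:
    chrom: str
    intron_start: int  # 0-based, first intronic base
    intron_end: int    # 0-based half-open, last intronic base + 1
    strand: str        # '+', '-' or '.' (unknown)
    left_flank: int    # nt of exonic evidence left of the intron (BED block 1)
    right_flank: int   # nt right of the intron (BED block 2)
    read_count: int = 0
    name: str = ""

    def validate(self) -> None:
        if self.intron_end - self.intron_start < 1:
            raise ValueError(f"{self.key()}: intron length must be >= 1")
        if self.left_flank < 1 or self.right_flank < 1:
            raise ValueError(f"{self.key()}: flank lengths must be >= 1")
        if self.strand not in "+-.":
            raise ValueError(f"{self.key()}: bad strand {self.strand!r}")

    def key(self) -> str:
        return f"{self.chrom}:{self.intron_start}-{self.intron_end}:{self.strand}"


def read_junction_bed(path: str | Path) -> list[SpliceJunction]:
    """Read a TopHat-style junctions BED12 (exactly two blocks per record).

    The intron is [chromStart + blockSize1, chromStart + blockStart2); the
    score column carries the supporting read count.
    """
    junctions: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            block_count = int(f[9])
            if block_count != 2:
                raise ValueError(
                    f"{path}:{lineno}: junction records need exactly 2 blocks, "
                    f"got {block_count}"
                )
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            j = SpliceJunction(
                chrom=f[0],
                intron_start=chrom_start + sizes[0],
                intron_end=chrom_start + starts[1],
                strand=f[5],
                left_flank=sizes[0],
                right_flank=sizes[1],
                read_count=int(float(f[4])),
                name=f[3],
            )
            j.validate()
            junctions.append(j)
    return junctions


def detect_novel_junctions(
    junctions: Iterable[SpliceJunction], annotation: GenomeAnnotation
) -> list[SpliceJunction]:
    """Junctions whose intron coordinates are absent from the gene model.

    Identity is (chromosome, intron start, intron end); strand is compared
    only when both the observed junction and the annotation know it. Input
    order is preserved.
    """
    annotated = annotation.annotated_introns()
    by_coords: dict[tuple[str, int, int], set[str]] = {}
    for chrom, s, e, strand in annotated:
        by_coords.setdefault((chrom, s, e), set()).add(strand)
    novel = []
    for j in junctions:
        strands = by_coords.get((j.chrom, j.intron_start, j.intron_end))
        if strands is None:
            novel.append(j)
        elif j.strand != "." and j.strand not in strands:
            novel.append(j)
    return novel


def _segments(protein: str) -> list[tuple[int, int]]:
    """Residue-index spans [i0, i1) of the stop-free segments of a translation."""
    spans, start = [], 0
    for i, aa in enumerate(protein):
        if aa == "*":
            if i > start:
                spans.append((start, i))
            start = i + 1
    if len(protein) > start:
        spans.append((start, len(protein)))
    return spans


def junction_entries(
    junction: SpliceJunction,
    chromosomes: Mapping[str, str],
    flank_nt: int = 66,
    min_length: int = 6,
) -> list[ProteinEntry]:
    """Translate the spliced junction context into SJ database entries.

    The context is min(flank_nt, BED flank, chromosome bounds) bases on each
    side of the intron, spliced together. Known strand: 3 frames ('-' strand
    reverse-complemented first); unknown: all 6. Each frame's translation is
    split at stops; a segment is kept when it spans the junction with >= 1
    residue on each side and reaches ``min_length``. Provenance records the
    junction key, orientation, frame, and the junction-residue span within
    the entry (0-based; jl == jr when one codon straddles the splice).
    """
    if flank_nt < 3:
        raise ValueError("flank_nt must be >= 3")
    junction.validate()
    chrom = chromosomes.get(junction.chrom)
    if chrom is None:
        raise KeyError(f"unknown chromosome {junction.chrom!r}")
    if junction.intron_start > len(chrom) or junction.intron_end > len(chrom):
        raise ValueError(f"junction {junction.key()} outside chromosome bounds")

    left_n = min(flank_nt, junction.left_flank, junction.intron_start)
    right_n = min(flank_nt, junction.right_flank, len(chrom) - junction.intron_end)
    left = chrom[junction.intron_start - left_n : junction.intron_start]
    right = chrom[junction.intron_end : junction.intron_end + right_n]
    context = left + right

    orientations: list[tuple[str, str, int]] = []  # (orient, seq, junction nt pos)
    if junction.strand in "+.":
        orientations.append(("+", context, len(left)))
    if junction.strand in "-.":
        orientations.append(("-", reverse_complement(context), len(right)))

    entries: list[ProteinEntry] = []
    n = 0
    for orient, seq, jpos in orientations:
        for frame in (0, 1, 2):
            protein = translate_nt(seq, frame)
            for i0, i1 in _segments(protein):
                # residue i occupies nt [frame + 3i, frame + 3i + 3)
                lefts = [i for i in range(i0, i1) if frame + 3 * i < jpos]
                rights = [i for i in range(i0, i1) if frame + 3 * i + 3 > jpos]
                if not lefts or not rights:
                    continue
                segment = protein[i0:i1]
                if len(segment) < min_length or "X" in segment:
                    continue
                jl, jr = max(lefts) - i0, min(rights) - i0
                n += 1
                entries.append(
                    ProteinEntry(
                        accession=(
                            f"SJ_{junction.chrom}_{junction.intron_start}_"
                            f"{junction.intron_end}_{orient}{frame}.{n}"
                        ),
                        sequence=segment,
                        origin="SJ",
                        provenance=(
                            f"{junction.key()};orient={orient};frame={frame};"
                            f"span={jl}-{jr}"
                        ),
                    )
                )
    return entries


def sj_junction_span(entry: ProteinEntry) -> tuple[int, int]:
    """0-based (left, right) junction-residue indices within an SJ entry."""
    m = SJ_PROV_RE.match(entry.provenance)
    if not m:
        raise ValueError(f"{entry.accession}: malformed SJ provenance")
    return int(m.group("jl")), int(m.group("jr"))


def build_sj_entries(
    junctions: Iterable[SpliceJunction],
    annotation: GenomeAnnotation,
    flank_nt: int = 66,
    min_length: int = 6,
) -> list[ProteinEntry]:
    """Convenience: detect novel junctions and translate them all."""
    out: list[ProteinEntry] = []
    for j in detect_novel_junctions(junctions, annotation):
        out.extend(junction_entries(j, annotation.chromosomes, flank_nt, min_length))
    return out
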