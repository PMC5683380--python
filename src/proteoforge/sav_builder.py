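"""Single-amino-acid-variant (SAV) database construction.

Exonic single-nucleotide variants are classified against the gene model
(strand-aware codon substitution) and every nonsynonymous effect is emitted
as a full-length variant protein carrying a ``p.<Ref><Pos><Alt>`` tag. One
substitution per entry — a transcript with several nsSNPs yields several
independent entries, never combinatorial haplotypes. Heterozygosity is
ignored: any called alternate allele produces an entry, while the reference
protein stays in the REF stream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from cyvcf2 import VCF

from .sequence_core import (
    AMINO_ACIDS,
    GenomeAnnotation,
    ProteinEntry,
    STOP,
    Transcript,
    spliced_cds_sequence,
    translate_nt,
)

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SAV_TAG_RE = re.compile(r"^p\.([A-Y])(\d+)([A-Y*])$")


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 0-based genomic coordinate
    ref_base: str
    alt_base: str
    sample: str = ""

    def validate(self) -> None:
        if len(self.ref_base) != 1 or len(self.alt_base) != 1:
            raise ValueError(f"{self}: single-nucleotide variants only")
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self}: ref and alt bases are identical")


@dataclass(frozen=True)
class VariantEffect:
    variant: VariantCall
    transcript_id: str | None
    cds_offset: int | None
    codon_index: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_residue: str | None
    alt_residue: str | None
    category: str  # synonymous | nonsynonymous | stop_gain | stop_loss | noncoding


def read_vcf(path: str | Path, sample: str = "") -> list[VariantCall]:
    """Read SNVs from a VCF v4.x file; multi-allelic records are split and
    non-SNV alleles (indels, MNVs) skipped."""
    calls: list[VariantCall] = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if len(rec.REF) == 1 and len(alt) == 1:
                calls.append(VariantCall(rec.CHROM, rec.POS - 1, rec.REF, alt, sample))
    return calls


def _cds_offset(t: Transcript, pos: int) -> int | None:
    """Offset of genomic ``pos`` within the spliced CDS, in transcription
    order, or None when the position is outside every CDS interval."""
    cds = sorted(t.cds)
    hit = next(((s, e) for s, e in cds if s <= pos < e), None)
    if hit is None:
        return None
    if t.strand == "+":
        before = sum(e - s for s, e in cds if e <= hit[0])
        return before + (pos - hit[0])
    before = sum(e - s for s, e in cds if s >= hit[1])
    return before + (hit[1] - 1 - pos)


def classify_variant_effect(
    annotation: GenomeAnnotation, variant: VariantCall
) -> list[VariantEffect]:
    """Classify a variant against every transcript whose CDS contains it.

    Returns one effect per overlapping transcript; a variant outside every
    CDS yields a single ``noncoding`` effect. The alternate base is
    complemented before codon substitution on '-'-strand transcripts.
    """
    variant.validate()
    chrom = annotation.chromosomes.get(variant.chrom)
    if chrom is None:
        raise KeyError(f"unknown chromosome {variant.chrom!r}")
    genome_base = chrom[variant.pos]
    if genome_base != variant.ref_base:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos}: ref base {variant.ref_base!r} "
            f"does not match genome base {genome_base!r}"
        )

    effects: list[VariantEffect] = []
    for t in annotation.transcripts():
        if t.chrom != variant.chrom or not t.cds:
            continue
        off = _cds_offset(t, variant.pos)
        if off is None:
            continue
        cds_seq = spliced_cds_sequence(annotation, t.transcript_id)
        ci = off // 3
        ref_codon = cds_seq[ci * 3 : ci * 3 + 3]
        if len(ref_codon) < 3:
            continue  # variant in a trailing partial codon
        alt_cds_base = variant.alt_base if t.strand == "+" else _COMP[variant.alt_base]
        within = off % 3
        alt_codon = ref_codon[:within] + alt_cds_base + ref_codon[within + 1 :]
        ref_res = translate_nt(ref_codon)
        alt_res = translate_nt(alt_codon)
        if ref_res == alt_res:
            category = "synonymous"
        elif ref_res != STOP and alt_res == STOP:
            category = "stop_gain"
        elif ref_res == STOP and alt_res != STOP:
            category = "stop_loss"
        else:
            category = "nonsynonymous"
        effects.append(
            VariantEffect(
                variant, t.transcript_id, off, ci, ref_codon, alt_codon,
                ref_res, alt_res, category,
            )
        )
    if not effects:
        effects.append(
            VariantEffect(variant, None, None, None, None, None, None, None, "noncoding")
        )
    return effects


def build_sav_entries(
    effects: list[VariantEffect],
    reference_proteome: Mapping[str, str],
    min_length: int = 6,
) -> list[ProteinEntry]:
    """Emit one SAV protein entry per nonsynonymous effect.

    The entry is the full-length reference protein with the single
    substitution applied (full length so that missed-cleavage peptides
    spanning the variant fall out of ordinary digestion). ``stop_gain``
    effects emit the truncated protein when it is at least ``min_length``
    residues; ``stop_loss`` is skipped (extension undefined) and logged.
    Identical (transcript, substitution) pairs are deduplicated.
    """
    entries: list[ProteinEntry] = []
    seen: set[tuple[str, str]] = set()
    for eff in effects:
        if eff.category in ("synonymous", "noncoding"):
            continue
        if eff.category == "stop_loss":
            log.info("skipping stop_loss variant on %s", eff.transcript_id)
            continue
        tid = eff.transcript_id
        if tid not in reference_proteome:
            raise KeyError(f"effect references unknown transcript {tid!r}")
        protein = reference_proteome[tid]
        ci = eff.codon_index
        if ci >= len(protein):
            raise ValueError(
                f"{tid}: codon index {ci} beyond protein of length {len(protein)}"
            )
        if protein[ci] != eff.ref_residue:
            raise ValueError(
                f"{tid}: reference protein has {protein[ci]!r} at residue "
                f"{ci + 1}, effect expects {eff.ref_residue!r}"
            )
        tag = f"p.{eff.ref_residue}{ci + 1}{eff.alt_residue}"
        key = (tid, tag)
        if key in seen:
            continue
        if eff.category == "stop_gain":
            seq = protein[:ci]
            if len(seq) < min_length:
                continue
        else:
            seq = protein[:ci] + eff.alt_residue + protein[ci + 1 :]
        seen.add(key)
        entries.append(
            ProteinEntry(
                accession=f"{tid}_{tag}",
                sequence=seq,
                origin="SAV",
                provenance=f"{tid};{tag}",
            )
        )
    return entries


def sav_variant_position(entry: ProteinEntry) -> int:
    """0-based residue index of the substitution recorded in an SAV entry."""
    tag = entry.provenance.split(";")[-1]
    m = SAV_TAG_RE.match(tag)
    if not m:
        raise ValueError(f"{entry.accession}: no substitution tag in provenance")
    return int(m.group(2)) - 1
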