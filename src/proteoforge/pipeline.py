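"""End-to-end assembly of the two search databases for one sample.

``build_sample_specific_database`` runs the three evidence workflows —
variant classification to SAV entries, novel-junction detection to SJ
entries, and TPM-based reduction of the reference stream — and
concatenates them, then appends reversed decoys. ``build_reference_database``
wraps the full reference proteome the same way.
"""

from __future__ import annotations

from pathlib import Path

from .abundance_reducer import read_tpm_table, reduce_by_tpm
from .db_assembler import SearchDatabase, add_decoys, assemble_database
from .sav_builder import build_sav_entries, classify_variant_effect, read_vcf
from .search_engine import SearchSettings
from .sequence_core import (
    GenomeAnnotation,
    ProteinEntry,
    spliced_cds_sequence,
    translate_nt,
)
from .sj_builder import build_sj_entries, read_junction_bed


def make_reference_entries(annotation: GenomeAnnotation) -> list[ProteinEntry]:
    """One REF entry per coding transcript, accessioned by transcript id."""
    entries = []
    for t in annotation.transcripts():
        if not t.cds:
            continue
        protein = translate_nt(
            spliced_cds_sequence(annotation, t.transcript_id),
            frame=t.frame,
            truncate_at_stop=True,
        )
        if not protein:
            continue
        entries.append(
            ProteinEntry(
                accession=t.transcript_id,
                sequence=protein,
                origin="REF",
                provenance=f"transcript={t.transcript_id}",
            )
        )
    return entries


def build_reference_database(
    annotation: GenomeAnnotation, name: str = "REFdb"
) -> SearchDatabase:
    db = assemble_database(make_reference_entries(annotation), name=name)
    return add_decoys(db)


def build_sample_specific_database(
    annotation: GenomeAnnotation,
    vcf_path: str | Path,
    junction_bed_path: str | Path,
    tpm_path: str | Path,
    name: str = "SSdb",
    tpm_threshold: float = 1.0,
    flank_nt: int = 66,
    settings: SearchSettings | None = None,
    sample: str = "",
) -> SearchDatabase:
    """SAV + SJ + TPM-reduced reference entries, concatenated, with decoys."""
    settings = settings or SearchSettings()
    min_len = settings.min_peptide_length

    ref_entries = make_reference_entries(annotation)
    proteome = {e.accession: e.sequence for e in ref_entries}

    effects = []
    for call in read_vcf(vcf_path, sample=sample):
        effects.extend(classify_variant_effect(annotation, call))
    sav_entries = build_sav_entries(effects, proteome, min_length=min_len)

    junctions = read_junction_bed(junction_bed_path)
    sj_entries = build_sj_entries(junctions, annotation, flank_nt=flank_nt,
                                  min_length=min_len)

    reduced = reduce_by_tpm(ref_entries, read_tpm_table(tpm_path),
                            threshold=tpm_threshold)
    db = assemble_database(reduced.entries, sav_entries, sj_entries, name=name)
    db.report["tpm_excluded"] = reduced.n_excluded_low
    db.report["tpm_missing"] = reduced.n_missing
    return add_decoys(db)
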