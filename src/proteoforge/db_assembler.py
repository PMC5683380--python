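"""Assembly of search databases and reversed-sequence decoys.

The three record streams (REF, SAV, SJ) are concatenated in that order into
one sample-specific database; the degenerate call with only reference
entries builds the REFdb. Decoys are full sequence reversals — the decoy
database therefore has exactly the target length distribution and
amino-acid composition, which keeps the target-decoy FDR estimate honest.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_core import ProteinEntry, read_protein_fasta, write_protein_fasta


@dataclass
class SearchDatabase:
    name: str
    entries: list[ProteinEntry] = field(default_factory=list)
    report: dict = field(default_factory=dict)

    @property
    def counts(self) -> Counter:
        return Counter(e.origin for e in self.entries)

    @property
    def targets(self) -> list[ProteinEntry]:
        return [e for e in self.entries if not e.is_decoy]

    def validate(self) -> None:
        seen = set()
        for e in self.entries:
            e.validate()
            if e.accession in seen:
                raise ValueError(f"duplicate accession {e.accession!r} in {self.name}")
            seen.add(e.accession)

    def write(self, path: str | Path) -> None:
        write_protein_fasta(self.entries, path)

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "SearchDatabase":
        return cls(name or str(path), read_protein_fasta(path))


def assemble_database(
    ref_entries: Sequence[ProteinEntry],
    sav_entries: Sequence[ProteinEntry] = (),
    sj_entries: Sequence[ProteinEntry] = (),
    name: str = "SSdb",
) -> SearchDatabase:
    """Concatenate REF, SAV and SJ streams into one database.

    Within a stream, exact duplicate sequences collapse to one entry with
    merged provenance. A SAV/SJ entry whose sequence equals a reference
    sequence carries no new information (the substitution was reverted by
    another convention, or the junction context is annotated sequence) and
    is dropped from its stream. Accession collisions are re-suffixed
    deterministically (_2, _3, ...).
    """
    if not (ref_entries or sav_entries or sj_entries):
        raise ValueError("cannot assemble an empty database")
    ref_sequences = {e.sequence for e in ref_entries}
    report = {"ref_in": len(ref_entries), "sav_in": len(sav_entries),
              "sj_in": len(sj_entries), "dropped_as_ref": 0,
              "merged_duplicates": 0, "accession_collisions": 0}

    merged: list[ProteinEntry] = []
    by_seq_origin: dict[tuple[str, str], ProteinEntry] = {}
    for stream in (ref_entries, sav_entries, sj_entries):
        for e in stream:
            e.validate()
            if e.origin != "REF" and e.sequence in ref_sequences:
                report["dropped_as_ref"] += 1
                continue
            key = (e.sequence, e.origin)
            prev = by_seq_origin.get(key)
            if prev is not None:
                if e.provenance and e.provenance not in prev.provenance:
                    prev.provenance = f"{prev.provenance};;{e.provenance}"
                report["merged_duplicates"] += 1
                continue
            copy = ProteinEntry(e.accession, e.sequence, e.origin,
                                e.provenance, e.description)
            by_seq_origin[key] = copy
            merged.append(copy)

    seen: set[str] = set()
    for e in merged:
        if e.accession in seen:
            i = 2
            while f"{e.accession}_{i}" in seen:
                i += 1
            e.accession = f"{e.accession}_{i}"
            report["accession_collisions"] += 1
        seen.add(e.accession)

    db = SearchDatabase(name, merged, report)
    report.update({f"n_{k.lower()}": v for k, v in db.counts.items()})
    db.validate()
    return db


def add_decoys(db: SearchDatabase) -> SearchDatabase:
    """Append one reversed-sequence decoy per target; |entries| doubles."""
    if any(e.is_decoy for e in db.entries):
        raise ValueError(f"{db.name} already contains decoy entries")
    decoys: list[ProteinEntry] = []
    palindromes = 0
    for e in db.entries:
        rev = e.sequence[::-1]
        if rev == e.sequence:
            palindromes += 1
        decoys.append(
            ProteinEntry(
                accession=f"DECOY_{e.accession}",
                sequence=rev,
                origin="DECOY",
                provenance=e.provenance,
                source_origin=e.origin,
            )
        )
    report = dict(db.report)
    report["palindromic_targets"] = palindromes
    out = SearchDatabase(db.name, db.entries + decoys, report)
    out.validate()
    return out


def reference_proteome(entries: Iterable[ProteinEntry]) -> dict[str, str]:
    """{accession: sequence} over the REF targets of a database or stream."""
    return {e.accession: e.sequence for e in entries if e.origin == "REF"}
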