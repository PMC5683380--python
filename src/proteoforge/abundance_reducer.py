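"""Transcript-abundance-based reduction of the reference protein stream.

Reference records whose transcripts are expressed below 1 TPM are excluded
from the sample-specific database. The boundary is literal: exactly 1.0 TPM
is retained, strictly less is excluded. Transcripts absent from the
abundance table are treated as unexpressed (RSEM quantifies every annotated
transcript, so absence means not quantified) and reported, not fatal.
Reduction applies to REF entries only — SAV and SJ records are already
evidence-backed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .sequence_core import ProteinEntry


@dataclass(frozen=True)
class AbundanceRecord:
    transcript_id: str
    tpm: float


@dataclass
class ReductionResult:
    entries: list[ProteinEntry]
    n_kept: int
    n_excluded_low: int
    n_missing: int
    missing_ids: list[str] = field(default_factory=list)


def read_tpm_table(path: str | Path) -> list[AbundanceRecord]:
    """Read an RSEM-style isoforms TSV; only transcript_id and TPM are used."""
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "TPM"):
        if col not in df.columns:
            raise ValueError(
                f"missing column {col!r}; available: {list(df.columns)}"
            )
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValueError(f"duplicate transcript ids in TPM table: {dups}")
    if (df["TPM"] < 0).any():
        raise ValueError("negative TPM values in table")
    return [
        AbundanceRecord(str(t), float(v))
        for t, v in zip(df["transcript_id"], df["TPM"])
    ]


def reduce_by_tpm(
    entries: Sequence[ProteinEntry],
    abundances: Sequence[AbundanceRecord],
    threshold: float = 1.0,
    transcript_of: Callable[[ProteinEntry], str] = lambda e: e.accession,
) -> ReductionResult:
    """Retain entries whose transcript TPM >= threshold, preserving order."""
    tpm = {a.transcript_id: a.tpm for a in abundances}
    kept: list[ProteinEntry] = []
    n_low = 0
    missing: list[str] = []
    for e in entries:
        tid = transcript_of(e)
        value = tpm.get(tid)
        if value is None:
            missing.append(tid)
        elif value >= threshold:
            kept.append(e)
        else:
            n_low += 1
    return ReductionResult(kept, len(kept), n_low, len(missing), missing)
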