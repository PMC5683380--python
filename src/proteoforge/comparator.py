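"""Cross-database comparison of accepted peptides.

Per-fraction PSM tables from both databases are merged under a unique
(sample, fraction, scan, database) key and rolled up to distinct peptide
sets per (sample, database). Peptides identified only by the
sample-specific database are then classified, in strict precedence order,
as reference-recovered (an exact substring of some reference protein — the
conservative call first, so nothing explainable by the reference is ever
called novel), SAV (maps to a variant entry with the substituted residue
inside the peptide), or novel-SJ (maps to a junction entry and spans the
junction residue pair).

Peptide identity throughout is the bare sequence — modifications stripped,
I and L kept distinct (MS cannot tell them apart, sequence databases can;
recorded caveat).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .db_assembler import SearchDatabase
from .sav_builder import sav_variant_position
from .sj_builder import sj_junction_span

CATEGORY_RECOVERED = "reference_recovered"
CATEGORY_SAV = "sav"
CATEGORY_SJ = "novel_sj"


@dataclass
class ComparisonResult:
    sample: str
    shared: set[str]
    ssdb_only: set[str]
    refdb_only: set[str]
    categories: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        parts = [self.categories.get(c, set()) for c in
                 (CATEGORY_RECOVERED, CATEGORY_SAV, CATEGORY_SJ)]
        union = set().union(*parts)
        if union != self.ssdb_only or sum(map(len, parts)) != len(self.ssdb_only):
            raise ValueError(
                f"{self.sample}: categories do not partition the SSdb-only set"
            )


def merge_psm_tables(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate labeled PSM tables; the (sample, fraction, scan_id,
    database) key must be unique across all inputs."""
    frames = [t for t in tables if len(t)]
    if not frames:
        return pd.DataFrame(
            columns=["sample", "fraction", "database", "scan_id", "peptide",
                     "is_decoy", "q_value"]
        )
    merged = pd.concat(frames, ignore_index=True)
    key = ["sample", "fraction", "scan_id", "database"]
    dup = merged.duplicated(subset=key)
    if dup.any():
        first = merged.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate PSM key across input tables: {first}")
    return merged


def peptide_rollup(
    merged: pd.DataFrame, max_q: float = 0.01
) -> dict[tuple[str, str], set[str]]:
    """Distinct accepted peptide sequences per (sample, database)."""
    ok = merged[(~merged["is_decoy"]) & (merged["q_value"] <= max_q)]
    out: dict[tuple[str, str], set[str]] = {}
    for (sample, database), grp in ok.groupby(["sample", "database"]):
        out[(sample, database)] = set(grp["peptide"])
    return out


def _occurrences(needle: str, haystack: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


class _ReferenceIndex:
    """Exact multi-pattern substring lookup over the reference proteome."""

    def __init__(self, proteome: Mapping[str, str]):
        # '|' never occurs in a protein sequence, so one concatenated string
        # gives an exact (and fast, via str.find) membership test
        self._blob = "|".join(proteome.values())

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._blob


def classify_unique_peptides(
    ssdb_peptides: set[str],
    refdb_peptides: set[str],
    ssdb: SearchDatabase,
    reference_proteome: Mapping[str, str],
    sample: str = "",
) -> ComparisonResult:
    """Partition SSdb-only peptides into the three evidence categories."""
    shared = ssdb_peptides & refdb_peptides
    ssdb_only = ssdb_peptides - refdb_peptides
    refdb_only = refdb_peptides - ssdb_peptides

    ref_index = _ReferenceIndex(reference_proteome)
    sav_entries = [e for e in ssdb.targets if e.origin == "SAV"]
    sj_entries = [e for e in ssdb.targets if e.origin == "SJ"]

    categories: dict[str, set[str]] = {
        CATEGORY_RECOVERED: set(), CATEGORY_SAV: set(), CATEGORY_SJ: set()
    }
    for pep in ssdb_only:
        if pep in ref_index:
            categories[CATEGORY_RECOVERED].add(pep)
            continue
        if any(_covers_variant(pep, e) for e in sav_entries):
            categories[CATEGORY_SAV].add(pep)
            continue
        if any(_spans_junction(pep, e) for e in sj_entries):
            categories[CATEGORY_SJ].add(pep)
            continue
        raise ValueError(
            f"SSdb-only peptide {pep!r} matches no reference protein, SAV "
            "record or SJ record — database/index inconsistency"
        )
    result = ComparisonResult(sample, shared, ssdb_only, refdb_only, categories)
    result.validate()
    return result


def _covers_variant(peptide: str, entry) -> bool:
    pos = sav_variant_position(entry)
    return any(o <= pos < o + len(peptide)
               for o in _occurrences(peptide, entry.sequence))


def _spans_junction(peptide: str, entry) -> bool:
    jl, jr = sj_junction_span(entry)
    return any(o <= jl and jr < o + len(peptide)
               for o in _occurrences(peptide, entry.sequence))


def venn_summary(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Per-sample and pooled partition counts plus category recurrence.

    The pooled row compares the unions of the per-sample peptide sets; the
    recurrence columns count category peptides seen in >= 2 samples.
    """
    rows = []
    for r in results:
        rows.append({
            "sample": r.sample,
            "ssdb_only": len(r.ssdb_only),
            "refdb_only": len(r.refdb_only),
            "shared": len(r.shared),
            "novel_sj": len(r.categories.get(CATEGORY_SJ, set())),
            "sav": len(r.categories.get(CATEGORY_SAV, set())),
            "reference_recovered": len(r.categories.get(CATEGORY_RECOVERED, set())),
        })
    ss_all = set().union(*(r.shared | r.ssdb_only for r in results))
    ref_all = set().union(*(r.shared | r.refdb_only for r in results))
    pooled = {
        "sample": "pooled",
        "ssdb_only": len(ss_all - ref_all),
        "refdb_only": len(ref_all - ss_all),
        "shared": len(ss_all & ref_all),
    }
    for cat, col in ((CATEGORY_SJ, "novel_sj"), (CATEGORY_SAV, "sav"),
                     (CATEGORY_RECOVERED, "reference_recovered")):
        union = set().union(*(r.categories.get(cat, set()) for r in results))
        recurrent = {
            pep for pep in union
            if sum(pep in r.categories.get(cat, set()) for r in results) >= 2
        }
        pooled[col] = len(union)
        pooled[f"{col}_recurrent"] = len(recurrent)
    rows.append(pooled)
    return pd.DataFrame(rows)
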