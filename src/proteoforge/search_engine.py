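"""Morpheus-style peptide-spectrum matching with target-decoy q-values.

The engine performs fully tryptic in-silico digestion (no proline rule, up
to 2 missed cleavages, variable initiator methionine), enumerates
modification isoforms (carbamidomethyl-C fixed, oxidation-M variable),
generates singly-charged b/y fragments, and scores each spectrum-candidate
pair as

    score = (# matched theoretical fragments) + (matched intensity / TIC)

so the integer part counts fragment evidence and the fractional part breaks
ties by explained ion current. Candidates are indexed by monoisotopic mass
and looked up in a ±2.1 Da precursor window (monoisotopic correction
disabled); q-values come from the decoy count / target count ratio at each
score threshold, monotonized.

Product peaks are treated as singly charged; true fragment charge
deconvolution is not implemented.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .db_assembler import SearchDatabase
from .sequence_core import ProteinEntry

log = logging.getLogger(__name__)

# Standard monoisotopic residue masses (Da).
MONOISOTOPIC_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565
PROTON = 1.007276

CARBAMIDOMETHYL = 57.02146  # fixed on C (iodoacetamide alkylation)
OXIDATION = 15.99491        # variable on M


@dataclass
class SearchSettings:
    """Complete search parameterization (defaults: the study's settings)."""

    min_precursor_charge: int = 2
    max_precursor_charge: int = 4
    max_peaks: int = 400
    assign_charge_states: bool = True  # product peaks treated as singly charged
    protease: str = "trypsin-no-proline-rule"
    max_missed_cleavages: int = 2
    initiator_methionine: str = "variable"
    fixed_mods: dict[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    variable_mods: dict[str, float] = field(
        default_factory=lambda: {"M": OXIDATION}
    )
    max_mod_isoforms: int = 1024
    precursor_tolerance_da: float = 2.1
    monoisotopic_correction: bool = False
    product_tolerance_da: float = 0.025
    max_fdr: float = 0.01
    min_peptide_length: int = 6
    max_peptide_length: int = 50

    def validate(self) -> None:
        if self.precursor_tolerance_da <= 0 or self.product_tolerance_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_precursor_charge > self.max_precursor_charge:
            raise ValueError("min precursor charge exceeds max")

    @classmethod
    def from_file(cls, path: str | Path) -> "SearchSettings":
        """Load settings from a YAML file keyed by the engine's names
        (e.g. 'Precursor Mass Tolerance', 'Maximum Missed Cleavages')."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        aliases = {
            "Assumed Precursor Charge States, Minimum": "min_precursor_charge",
            "Assumed Precursor Charge States, Maximum": "max_precursor_charge",
            "MS/MS Peak Filtering, Maximum Number of Peaks": "max_peaks",
            "MS/MS Analysis, Assign Charge States": "assign_charge_states",
            "Protease": "protease",
            "Maximum Missed Cleavages": "max_missed_cleavages",
            "Initiator Methionine Behavior": "initiator_methionine",
            "Maximum Variable Modification Isoforms Per Peptide": "max_mod_isoforms",
            "Precursor Mass Tolerance": "precursor_tolerance_da",
            "Precursor Monoisotopic Peak Correction": "monoisotopic_correction",
            "Product Mass Tolerance": "product_tolerance_da",
            "Maximum False Discovery Rate": "max_fdr",
            "Minimum Peptide Length": "min_peptide_length",
            "Maximum Peptide Length": "max_peptide_length",
        }
        kwargs = {}
        for key, value in data.items():
            attr = aliases.get(key, key)
            if not hasattr(cls(), attr):
                raise ValueError(f"unknown setting {key!r}")
            kwargs[attr] = value
        s = cls(**kwargs)
        s.validate()
        return s


@dataclass
class Spectrum:
    scan_id: str
    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def validate(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError(f"{self.scan_id}: peak array length mismatch")
        if np.any(np.diff(self.mz) < 0):
            raise ValueError(f"{self.scan_id}: peaks not sorted by m/z")
        if len(self.intensity) and self.intensity.min() <= 0:
            raise ValueError(f"{self.scan_id}: non-positive peak intensity")


@dataclass(frozen=True)
class PeptideCandidate:
    sequence: str
    proteins: tuple[str, ...]          # parent accessions, sorted
    missed_cleavages: int
    start: int                         # 0-based start within the first parent
    mods: tuple[tuple[int, float], ...] = ()  # (site index, mass delta), sorted

    @property
    def is_decoy(self) -> bool:
        return all(p.startswith("DECOY_") for p in self.proteins)

    def mod_string(self) -> str:
        return ",".join(f"{i}:{d:+.5f}" for i, d in self.mods)


@dataclass
class PSM:
    scan_id: str
    candidate: PeptideCandidate
    charge: int
    score: float
    is_decoy: bool
    q_value: float = float("nan")
    precursor_neutral_mass: float = float("nan")


# --------------------------------------------------------------------------
# Digestion and modification isoforms
# --------------------------------------------------------------------------

def digest_protein(entry: ProteinEntry, settings: SearchSettings) -> list[PeptideCandidate]:
    """Fully tryptic digestion of one protein.

    Cleaves after every K/R — including before proline (the no-proline
    rule). Emits every product with 0..max missed cleavages; for
    protein-N-terminal peptides starting with M both the retained and
    trimmed forms are emitted ('variable' initiator behavior). Peptides
    outside the length bounds or containing 'X' are dropped.
    """
    seq = entry.sequence
    sites = [i + 1 for i, aa in enumerate(seq) if aa in "KR"]
    boundaries = [0] + [s for s in sites if s < len(seq)] + [len(seq)]
    lo, hi = settings.min_peptide_length, settings.max_peptide_length
    out: list[PeptideCandidate] = []

    def emit(pep: str, start: int, missed: int) -> None:
        if lo <= len(pep) <= hi and "X" not in pep:
            out.append(PeptideCandidate(pep, (entry.accession,), missed, start))

    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + settings.max_missed_cleavages,
                                  len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            missed = j - i - 1
            pep = seq[start:end]
            emit(pep, start, missed)
            if (start == 0 and pep.startswith("M") and len(pep) > 1
                    and settings.initiator_methionine == "variable"):
                emit(pep[1:], 1, missed)
    return out


def enumerate_mod_isoforms(
    candidate: PeptideCandidate, settings: SearchSettings
) -> list[PeptideCandidate]:
    """All modification isoforms of an unmodified candidate.

    Fixed modifications apply to every matching residue unconditionally;
    one isoform is emitted per subset of variable-mod sites, enumerated in
    binary-counting order over sites sorted ascending, capped at the
    isoform limit (truncation logged).
    """
    if candidate.mods:
        raise ValueError("candidate already carries modifications")
    fixed = tuple(
        (i, settings.fixed_mods[aa])
        for i, aa in enumerate(candidate.sequence)
        if aa in settings.fixed_mods
    )
    var_sites = [
        (i, settings.variable_mods[aa])
        for i, aa in enumerate(candidate.sequence)
        if aa in settings.variable_mods
    ]
    m = len(var_sites)
    n_subsets = 1 << m
    if n_subsets > settings.max_mod_isoforms:
        log.info(
            "peptide %s: %d variable-mod isoforms truncated to %d",
            candidate.sequence, n_subsets, settings.max_mod_isoforms,
        )
        n_subsets = settings.max_mod_isoforms
    isoforms = []
    for mask in range(n_subsets):
        var = tuple(var_sites[b] for b in range(m) if mask >> b & 1)
        mods = tuple(sorted(fixed + var))
        isoforms.append(replace(candidate, mods=mods))
    return isoforms


# --------------------------------------------------------------------------
# Masses and fragments
# --------------------------------------------------------------------------

def peptide_monoisotopic_mass(
    candidate: PeptideCandidate,
    masses: Mapping[str, float] = MONOISOTOPIC_MASSES,
) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    return (
        sum(masses[aa] for aa in candidate.sequence)
        + WATER
        + sum(d for _, d in candidate.mods)
    )


def theoretical_fragments(
    candidate: PeptideCandidate,
    masses: Mapping[str, float] = MONOISOTOPIC_MASSES,
) -> list[tuple[str, int, float]]:
    """Singly-charged b and y ions for indices 1..n-1, with site mods
    included in the covering prefix/suffix."""
    seq = candidate.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("fragments require peptide length >= 2")
    deltas = np.zeros(n)
    for i, d in candidate.mods:
        deltas[i] += d
    residue = np.array([masses[aa] for aa in seq]) + deltas
    prefix = np.cumsum(residue)
    total = prefix[-1]
    frags: list[tuple[str, int, float]] = []
    for i in range(1, n):
        frags.append(("b", i, prefix[i - 1] + PROTON))
        frags.append(("y", i, total - prefix[n - i - 1] + WATER + PROTON))
    return frags


# --------------------------------------------------------------------------
# Spectrum handling and scoring
# --------------------------------------------------------------------------

def preprocess_spectrum(spectrum: Spectrum, settings: SearchSettings) -> Spectrum:
    """Keep the most intense ``max_peaks`` peaks (intensity ties broken by
    lower m/z first), re-sorted by m/z."""
    spectrum.validate()
    k = settings.max_peaks
    if len(spectrum.mz) <= k:
        return spectrum
    order = np.lexsort((spectrum.mz, -spectrum.intensity))[:k]
    keep = np.sort(order)
    return replace(spectrum, mz=spectrum.mz[keep], intensity=spectrum.intensity[keep])


def _match_fragments(
    frag_mz: Sequence[float],
    peaks_mz: np.ndarray,
    peaks_int: np.ndarray,
    tol: float,
) -> tuple[int, float]:
    """Greedy nearest-peak assignment, one peak per fragment; equal-distance
    ties go to the lower-m/z peak. Returns (matched count, matched intensity)."""
    used: set[int] = set()
    matched = 0
    matched_intensity = 0.0
    for fmz in sorted(frag_mz):
        lo = bisect_left(peaks_mz, fmz - tol)
        hi = bisect_right(peaks_mz, fmz + tol)
        best = -1
        best_d = None
        for idx in range(lo, hi):
            if idx in used:
                continue
            d = abs(peaks_mz[idx] - fmz)
            if best_d is None or d < best_d - 1e-12:
                best, best_d = idx, d
        if best >= 0:
            used.add(best)
            matched += 1
            matched_intensity += float(peaks_int[best])
    return matched, matched_intensity


def score_psm(
    spectrum: Spectrum,
    candidate: PeptideCandidate,
    settings: SearchSettings,
    masses: Mapping[str, float] = MONOISOTOPIC_MASSES,
) -> float:
    """Matched-fragment count plus matched-intensity fraction of TIC."""
    if len(spectrum.mz) == 0:
        raise ValueError(f"{spectrum.scan_id}: empty spectrum")
    frags = [mz for _, _, mz in theoretical_fragments(candidate, masses)]
    n, inten = _match_fragments(
        frags, spectrum.mz, spectrum.intensity, settings.product_tolerance_da
    )
    return n + inten / spectrum.tic


# --------------------------------------------------------------------------
# The search proper
# --------------------------------------------------------------------------

class CandidateIndex:
    """All digested, modified candidates of a database, sorted by mass.

    Identical (sequence, modification vector) candidates from different
    proteins collapse to one candidate carrying every parent accession; a
    candidate is a decoy only when all its parents are decoys.
    """

    def __init__(
        self,
        db: SearchDatabase,
        settings: SearchSettings,
        masses: Mapping[str, float] = MONOISOTOPIC_MASSES,
    ):
        merged: dict[tuple[str, tuple], PeptideCandidate] = {}
        for entry in db.entries:
            for cand in digest_protein(entry, settings):
                for iso in enumerate_mod_isoforms(cand, settings):
                    key = (iso.sequence, iso.mods)
                    prev = merged.get(key)
                    if prev is None:
                        merged[key] = iso
                    elif iso.proteins[0] not in prev.proteins:
                        merged[key] = replace(
                            prev,
                            proteins=tuple(sorted(prev.proteins + iso.proteins)),
                        )
        cands = list(merged.values())
        mass = np.array([peptide_monoisotopic_mass(c, masses) for c in cands])
        order = np.argsort(mass, kind="stable")
        self.candidates = [cands[i] for i in order]
        self.masses = mass[order]

    def __len__(self) -> int:
        return len(self.candidates)

    def window(self, neutral_mass: float, tol: float) -> range:
        lo = int(np.searchsorted(self.masses, neutral_mass - tol, side="left"))
        hi = int(np.searchsorted(self.masses, neutral_mass + tol, side="right"))
        return range(lo, hi)


def run_search(
    db: SearchDatabase,
    spectra: Iterable[Spectrum],
    settings: SearchSettings | None = None,
    masses: Mapping[str, float] = MONOISOTOPIC_MASSES,
    index: CandidateIndex | None = None,
) -> list[PSM]:
    """Best PSM per spectrum against a target+decoy database.

    A known precursor charge is used as-is; otherwise every charge in the
    assumed range is evaluated. Neutral mass = z·(m/z) − z·proton; candidates
    within the precursor tolerance are scored and the best kept (score ties:
    target over decoy, then lexicographically smallest peptide). No isotope
    offsets are tried (monoisotopic correction disabled).
    """
    settings = settings or SearchSettings()
    settings.validate()
    if index is None:
        index = CandidateIndex(db, settings, masses)
    psms: list[PSM] = []
    n_unmatched = 0
    for raw in spectra:
        spec = preprocess_spectrum(raw, settings)
        if spec.precursor_charge:
            charges = [spec.precursor_charge]
        else:
            charges = list(
                range(settings.min_precursor_charge, settings.max_precursor_charge + 1)
            )
        best: PSM | None = None
        for z in charges:
            neutral = z * spec.precursor_mz - z * PROTON
            for i in index.window(neutral, settings.precursor_tolerance_da):
                cand = index.candidates[i]
                s = score_psm(spec, cand, settings, masses)
                contender = PSM(spec.scan_id, cand, z, s, cand.is_decoy,
                                precursor_neutral_mass=neutral)
                if best is None or _psm_beats(contender, best):
                    best = contender
        if best is None:
            n_unmatched += 1
        else:
            psms.append(best)
    if n_unmatched:
        log.info("%d spectra had no candidate in the precursor window", n_unmatched)
    return psms


def _psm_beats(a: PSM, b: PSM) -> bool:
    ka = (a.score, not a.is_decoy, _neg_lex(a.candidate.sequence))
    kb = (b.score, not b.is_decoy, _neg_lex(b.candidate.sequence))
    return ka > kb


def _neg_lex(s: str) -> tuple:
    # smaller-lexicographic wins inside a max comparison
    return tuple(-ord(c) for c in s)


def compute_q_values(psms: list[PSM], settings: SearchSettings | None = None) -> list[PSM]:
    """Fill q-values on a best-PSM-per-spectrum list.

    At each score threshold FDR = decoys ≥ t / targets ≥ t (0 when no
    targets); ties share one threshold. A PSM's q-value is the minimum FDR
    over thresholds at or below its score.
    """
    ordered = sorted(psms, key=lambda p: -p.score)
    # FDR at each unique score, walking down the sorted list with ties grouped
    fdrs: list[float] = []
    spans: list[tuple[int, int]] = []
    d = t = 0
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j].score == ordered[i].score:
            d += ordered[j].is_decoy
            t += not ordered[j].is_decoy
            j += 1
        fdrs.append(0.0 if t == 0 else d / t)
        spans.append((i, j))
        i = j
    # min over thresholds at or below: suffix minimum, capped at 1
    running = float("inf")
    for k in range(len(fdrs) - 1, -1, -1):
        running = min(running, fdrs[k])
        q = min(running, 1.0)
        for idx in range(*spans[k]):
            ordered[idx].q_value = q
    return ordered


def accepted_psms(psms: Iterable[PSM], settings: SearchSettings | None = None) -> list[PSM]:
    """Target PSMs at or below the FDR cap."""
    cap = (settings or SearchSettings()).max_fdr
    return [p for p in psms if not p.is_decoy and p.q_value <= cap]


# --------------------------------------------------------------------------
# Protein grouping
# --------------------------------------------------------------------------

@dataclass
class ProteinGroup:
    accessions: tuple[str, ...]
    peptides: frozenset


def group_proteins(psms: Iterable[PSM], db: SearchDatabase) -> list[ProteinGroup]:
    """Parsimonious protein groups from accepted PSMs.

    Peptides map to every target protein containing them as a substring;
    proteins with identical peptide sets merge into one group, and a group
    whose peptide set is a strict subset of another's is discarded.
    Deterministic ordering by accession.
    """
    peptides = {p.candidate.sequence for p in psms}
    by_protein: dict[str, set[str]] = {}
    for e in db.targets:
        hits = {pep for pep in peptides if pep in e.sequence}
        if hits:
            by_protein[e.accession] = hits
    by_set: dict[frozenset, list[str]] = {}
    for acc in sorted(by_protein):
        by_set.setdefault(frozenset(by_protein[acc]), []).append(acc)
    groups = [ProteinGroup(tuple(sorted(accs)), peps) for peps, accs in by_set.items()]
    groups.sort(key=lambda g: (-len(g.peptides), g.accessions))
    kept: list[ProteinGroup] = []
    for g in groups:
        if not any(g.peptides < other.peptides for other in kept):
            kept.append(g)
    return kept


# --------------------------------------------------------------------------
# I/O: MGF spectra in, PSM tables out
# --------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read MS/MS spectra from an MGF file (TITLE/PEPMASS/CHARGE)."""
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, rec in enumerate(reader):
            params = rec["params"]
            charge = params.get("charge")
            z = int(charge[0]) if charge else None
            mz = np.asarray(rec["m/z array"], dtype=float)
            inten = np.asarray(rec["intensity array"], dtype=float)
            keep = inten > 0
            order = np.argsort(mz[keep], kind="stable")
            spec = Spectrum(
                scan_id=str(params.get("title", f"index={i}")),
                precursor_mz=float(params["pepmass"][0]),
                precursor_charge=z,
                mz=mz[keep][order],
                intensity=inten[keep][order],
            )
            spec.validate()
            spectra.append(spec)
    return spectra


def psms_to_table(
    psms: Iterable[PSM], sample: str = "", fraction: str = "", database: str = ""
) -> pd.DataFrame:
    """PSM table in the style of a Morpheus .PSMs.tsv, plus run labels."""
    rows = [
        {
            "sample": sample,
            "fraction": fraction,
            "database": database,
            "scan_id": p.scan_id,
            "peptide": p.candidate.sequence,
            "modifications": p.candidate.mod_string(),
            "proteins": ";".join(p.candidate.proteins),
            "charge": p.charge,
            "score": p.score,
            "is_decoy": p.is_decoy,
            "q_value": p.q_value,
        }
        for p in psms
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "fraction", "database", "scan_id", "peptide",
                 "modifications", "proteins", "charge", "score", "is_decoy",
                 "q_value"],
    )
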