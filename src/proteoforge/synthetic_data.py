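"""Synthetic genome, RNA-Seq evidence and MS/MS spectra with ground truth.

The generator emulates the statistical structure the pipeline consumes: a
toy genome of multi-exon genes on both strands (ATG-initiated, stop-
terminated, codon-aligned exons), planted nonsynonymous and synonymous
SNVs with their intended codon effect verified at generation time, planted
exon-skipping junctions absent from the annotation (exon skipping reuses
annotated splice sites, so the in-frame translated context is known
exactly), log-normal transcript abundances with a stated fraction below
1 TPM, and simulated tryptic-peptide spectra with Gaussian fragment m/z
jitter, dropped peaks and uniform noise peaks, plus spectra of foreign
peptides absent from the database. Every emitted spectrum is covered by a
truth manifest, which is the oracle for end-to-end and FDR tests.

All randomness flows from one seeded NumPy generator per call; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .db_assembler import SearchDatabase
from .sav_builder import sav_variant_position
from .search_engine import (
    PROTON,
    PeptideCandidate,
    SearchSettings,
    Spectrum,
    digest_protein,
    peptide_monoisotopic_mass,
    theoretical_fragments,
)
from .sequence_core import (
    CODON_TABLE,
    GenomeAnnotation,
    Gene,
    ProteinEntry,
    Transcript,
    reverse_complement,
    spliced_cds_sequence,
    translate_nt,
)
from .sj_builder import sj_junction_span

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = sorted(c for c in CODON_TABLE if c not in _STOPS)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticGeneLayout:
    """Book-keeping the generator needs beyond the public annotation."""

    transcript_id: str
    strand: str
    chunks: list[str]  # coding chunks per exon, transcription order, codon-aligned
    exon_coords: list[tuple[int, int]]  # genomic, ascending


@dataclass
class SyntheticTruth:
    annotation: GenomeAnnotation
    proteins: dict[str, str]
    layouts: dict[str, SyntheticGeneLayout]
    planted_nssnps: list[dict] = field(default_factory=list)
    planted_synonymous: list[dict] = field(default_factory=list)
    planted_junctions: list[dict] = field(default_factory=list)
    tpm: dict[str, float] = field(default_factory=dict)
    low_tpm_ids: set[str] = field(default_factory=set)
    spectra_truth: dict[str, dict] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def simulate_genome_and_truth(
    n_genes: int = 20,
    exons_per_gene: int = 3,
    seed: int = 0,
    codons_per_exon: tuple[int, int] = (22, 40),
    intron_length: tuple[int, int] = (60, 140),
    intergenic_length: tuple[int, int] = (200, 400),
    n_chromosomes: int = 2,
    out_dir: str | Path | None = None,
) -> SyntheticTruth:
    """Build a toy genome with fully-coding multi-exon genes on both strands.

    Exons are codon-aligned (each a whole number of codons, at least 22 so
    that a 66-nt junction flank is never truncated) which makes the
    translation of any exon-skipping junction predictable. Writes
    ``genome.fasta`` and ``annotation.gtf`` when ``out_dir`` is given.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(n_chromosomes)
    }
    cursors = {c: 0 for c in chrom_parts}
    genes: list[Gene] = []
    proteins: dict[str, str] = {}
    layouts: dict[str, SyntheticGeneLayout] = {}

    for gi in range(n_genes):
        chrom = f"chr{(gi % n_chromosomes) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id, tid = f"G{gi + 1:03d}", f"T{gi + 1:03d}"
        n_codons_per_exon = rng.integers(
            codons_per_exon[0], codons_per_exon[1] + 1, size=exons_per_gene
        )
        codons = ["ATG"]
        n_total = int(n_codons_per_exon.sum())
        codons += [
            _NON_STOP_CODONS[k]
            for k in rng.integers(0, len(_NON_STOP_CODONS), size=n_total - 2)
        ]
        codons.append("TAA")
        chunks, off = [], 0
        for nc in n_codons_per_exon:
            chunks.append("".join(codons[off : off + int(nc)]))
            off += int(nc)

        genomic_chunks = (
            chunks if strand == "+" else [reverse_complement(c) for c in chunks[::-1]]
        )
        pos = cursors[chrom] + int(rng.integers(*intergenic_length))
        coords: list[tuple[int, int]] = []
        parts = chrom_parts[chrom]
        parts.append(_random_seq(rng, pos - cursors[chrom]))
        for k, gchunk in enumerate(genomic_chunks):
            coords.append((pos, pos + len(gchunk)))
            parts.append(gchunk)
            pos += len(gchunk)
            if k < len(genomic_chunks) - 1:
                ilen = int(rng.integers(*intron_length))
                parts.append(_random_seq(rng, ilen))
                pos += ilen
        cursors[chrom] = pos

        t = Transcript(tid, gene_id, chrom, strand, exons=list(coords),
                       cds=list(coords))
        genes.append(Gene(gene_id, chrom, strand, [t]))
        layouts[tid] = SyntheticGeneLayout(tid, strand, chunks, coords)

    chromosomes = {
        c: "".join(parts) + _random_seq(rng, 100) for c, parts in chrom_parts.items()
    }
    annotation = GenomeAnnotation(chromosomes, genes)
    annotation.validate()
    for t in annotation.transcripts():
        prot = translate_nt(spliced_cds_sequence(annotation, t.transcript_id),
                            truncate_at_stop=True)
        if "*" in prot or not prot.startswith("M"):
            raise AssertionError(f"generator produced invalid CDS for {t.transcript_id}")
        proteins[t.transcript_id] = prot

    truth = SyntheticTruth(annotation, proteins, layouts)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .sequence_core import write_genome_fasta

        write_genome_fasta(chromosomes, out_dir / "genome.fasta")
        write_gtf(annotation, out_dir / "annotation.gtf")
    return truth


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Emit the annotation as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for gene in annotation.genes:
            for t in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                for ftype, ivs in (("exon", t.exons), ("CDS", t.cds)):
                    for s, e in sorted(ivs):
                        frame = "0" if ftype == "CDS" else "."
                        fh.write(
                            f"{t.chrom}\tsynthetic\t{ftype}\t{s + 1}\t{e}\t.\t"
                            f"{t.strand}\t{frame}\t{attrs}\n"
                        )


def _cds_offset_to_genomic(t: Transcript, off: int) -> int:
    cds = sorted(t.cds)
    if t.strand == "+":
        for s, e in cds:
            if off < e - s:
                return s + off
            off -= e - s
    else:
        for s, e in reversed(cds):
            if off < e - s:
                return e - 1 - off
            off -= e - s
    raise ValueError("CDS offset beyond transcript")


def _plant_snvs(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    n: int,
    synonymous: bool,
) -> list[dict]:
    """Place SNVs with the requested codon-level effect, verified via the
    codon table at generation time."""
    ann = truth.annotation
    tids = sorted(truth.layouts)
    used_codons = {(v["transcript_id"], v["codon_index"])
                   for v in truth.planted_nssnps + truth.planted_synonymous}
    used_pos = {(v["chrom"], v["pos"])
                for v in truth.planted_nssnps + truth.planted_synonymous}
    planted: list[dict] = []
    attempts = 0
    while len(planted) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError("could not place requested SNVs")
        tid = tids[int(rng.integers(len(tids)))]
        t = ann.transcript(tid)
        protein = truth.proteins[tid]
        ci = int(rng.integers(1, len(protein)))  # skip the initiator Met
        if (tid, ci) in used_codons:
            continue
        cds_seq = spliced_cds_sequence(ann, tid)
        ref_codon = cds_seq[ci * 3 : ci * 3 + 3]
        within = int(rng.integers(3))
        ref_base = ref_codon[within]
        alts = [b for b in "ACGT" if b != ref_base]
        rng.shuffle(alts)
        hit = None
        for alt in alts:
            alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
            ref_res, alt_res = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
            same = ref_res == alt_res
            if synonymous and same:
                hit = (alt, alt_codon, ref_res, alt_res)
                break
            if not synonymous and not same and alt_res != "*" and ref_res != "*":
                hit = (alt, alt_codon, ref_res, alt_res)
                break
        if hit is None:
            continue
        alt, alt_codon, ref_res, alt_res = hit
        pos = _cds_offset_to_genomic(t, ci * 3 + within)
        if (t.chrom, pos) in used_pos:
            continue
        genome_ref = ann.chromosomes[t.chrom][pos]
        genome_alt = alt if t.strand == "+" else _COMP[alt]
        assert genome_ref == (ref_base if t.strand == "+" else _COMP[ref_base])
        used_codons.add((tid, ci))
        used_pos.add((t.chrom, pos))
        planted.append({
            "chrom": t.chrom, "pos": pos, "ref": genome_ref, "alt": genome_alt,
            "transcript_id": tid, "codon_index": ci,
            "tag": f"p.{ref_res}{ci + 1}{alt_res}",
            "category": "synonymous" if synonymous else "nonsynonymous",
        })
    return planted


def _expected_junction_peptide(layout: SyntheticGeneLayout, skip_k: int,
                               flank_nt: int = 66) -> tuple[str, int, int]:
    """In-frame translation of the exon-skipping junction context.

    Returns (peptide, jl, jr): the stop-free segment spanning the junction
    and the 0-based junction-residue indices within it.
    """
    up = layout.chunks[skip_k - 1][-flank_nt:]
    down = layout.chunks[skip_k + 1][:flank_nt]
    protein = translate_nt(up + down)  # codon-aligned, frame 0
    jl = len(up) // 3 - 1
    jr = jl + 1
    start = 0
    for i, aa in enumerate(protein):
        if aa == "*":
            if start <= jl and jr < i:
                return protein[start:i], jl - start, jr - start
            start = i + 1
    if start <= jl and jr < len(protein):
        return protein[start:], jl - start, jr - start
    raise AssertionError("junction context translation lost the junction")


def simulate_sample_evidence(
    truth: SyntheticTruth,
    n_nssnp: int = 10,
    n_synonymous: int = 5,
    n_novel_junctions: int = 5,
    low_tpm_fraction: float = 0.3,
    tpm_mu: float = 1.5,
    tpm_sigma: float = 1.5,
    seed: int = 0,
    junction_flank: int = 80,
    out_dir: str | Path | None = None,
) -> dict[str, Path] | None:
    """Plant per-sample evidence into ``truth`` and emit VCF/BED/TSV files.

    Novel junctions skip one internal exon, joining the annotated donor of
    the upstream exon to the annotated acceptor of the downstream exon.
    Annotated junctions are also emitted in the BED so that novelty
    detection is non-trivial. TPM values are log-normal, rescaled by the
    k-th order statistic so exactly round(fraction*n) transcripts fall
    strictly below 1 TPM and one sits exactly on the boundary.
    """
    rng = np.random.default_rng(seed)
    ann = truth.annotation

    truth.planted_nssnps = _plant_snvs(truth, rng, n_nssnp, synonymous=False)
    truth.planted_synonymous = _plant_snvs(truth, rng, n_synonymous, synonymous=True)

    eligible = sorted(
        tid for tid, lay in truth.layouts.items() if len(lay.chunks) >= 3
    )
    if n_novel_junctions > len(eligible):
        raise ValueError("not enough multi-exon genes for requested junctions")
    chosen = [eligible[i] for i in
              rng.choice(len(eligible), size=n_novel_junctions, replace=False)]
    truth.planted_junctions = []
    for tid in sorted(chosen):
        lay = truth.layouts[tid]
        n_e = len(lay.chunks)
        k = int(rng.integers(1, n_e - 1))  # transcription-order internal exon
        g = n_e - 1 - k if lay.strand == "-" else k  # genomic index of skipped exon
        intron_start = lay.exon_coords[g - 1][1]
        intron_end = lay.exon_coords[g + 1][0]
        pep, jl, jr = _expected_junction_peptide(lay, k)
        t = ann.transcript(tid)
        truth.planted_junctions.append({
            "chrom": t.chrom, "intron_start": intron_start,
            "intron_end": intron_end, "strand": lay.strand,
            "transcript_id": tid, "skipped_exon": k,
            "expected_peptide": pep, "expected_span": (jl, jr),
        })

    tids = sorted(truth.proteins)
    values = rng.lognormal(mean=tpm_mu, sigma=tpm_sigma, size=len(tids))
    k_low = int(round(low_tpm_fraction * len(tids)))
    if 0 < k_low < len(tids):
        scale = float(np.sort(values)[k_low])
        values = values / scale
    truth.tpm = {tid: float(v) for tid, v in zip(tids, values)}
    truth.low_tpm_ids = {tid for tid, v in truth.tpm.items() if v < 1.0}

    if out_dir is None:
        return None
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "sample.vcf",
        "bed": out_dir / "junctions.bed",
        "tpm": out_dir / "abundance.isoforms.results",
    }
    _write_vcf(truth, paths["vcf"])
    _write_junction_bed(truth, rng, paths["bed"], junction_flank)
    _write_tpm_table(truth, rng, paths["tpm"])
    return paths


def _write_vcf(truth: SyntheticTruth, path: Path) -> None:
    records = sorted(
        truth.planted_nssnps + truth.planted_synonymous,
        key=lambda v: (v["chrom"], v["pos"]),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in truth.annotation.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in records:
            fh.write(
                f"{v['chrom']}\t{v['pos'] + 1}\t.\t{v['ref']}\t{v['alt']}\t"
                "50\tPASS\t.\n"
            )


def _bed_line(chrom: str, intron_start: int, intron_end: int, strand: str,
              name: str, count: int, left: int, right: int) -> str:
    start = intron_start - left
    end = intron_end + right
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t{count}\t{strand}\t{start}\t{end}\t"
        f"255,0,0\t2\t{left},{right}\t0,{intron_end - start}\n"
    )


def _write_junction_bed(truth: SyntheticTruth, rng: np.random.Generator,
                        path: Path, flank: int) -> None:
    lines: list[tuple] = []
    for j in truth.planted_junctions:
        lay = truth.layouts[j["transcript_id"]]
        coords = lay.exon_coords
        g_left = max(i for i, (s, e) in enumerate(coords) if e <= j["intron_start"])
        g_right = min(i for i, (s, e) in enumerate(coords) if s >= j["intron_end"])
        left = min(flank, coords[g_left][1] - coords[g_left][0])
        right = min(flank, coords[g_right][1] - coords[g_right][0])
        lines.append((j["chrom"], j["intron_start"], j["intron_end"], j["strand"],
                      left, right))
    for t in truth.annotation.transcripts():
        exons = sorted(t.exons)
        for i, (s, e) in enumerate(t.introns()):
            left = min(flank, exons[i][1] - exons[i][0])
            right = min(flank, exons[i + 1][1] - exons[i + 1][0])
            lines.append((t.chrom, s, e, t.strand, left, right))
    lines.sort(key=lambda x: (x[0], x[1], x[2]))
    with open(path, "w") as fh:
        for n, (chrom, s, e, strand, left, right) in enumerate(lines, 1):
            count = int(rng.integers(3, 60))
            fh.write(_bed_line(chrom, s, e, strand, f"JUNC{n:05d}", count,
                               left, right))


def _write_tpm_table(truth: SyntheticTruth, rng: np.random.Generator,
                     path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tlength\teffective_length\t"
                 "expected_count\tTPM\tFPKM\tIsoPct\n")
        for tid in sorted(truth.tpm):
            t = truth.annotation.transcript(tid)
            length = sum(e - s for s, e in t.exons)
            tpm = truth.tpm[tid]
            count = tpm * length / 1000.0
            fh.write(
                f"{tid}\t{t.gene_id}\t{length}\t{max(length - 150, 1)}\t"
                f"{count:.2f}\t{tpm:.6f}\t{tpm * 0.9:.6f}\t100.00\n"
            )


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------

def _fragment_mzs(sequence: str, settings: SearchSettings) -> np.ndarray:
    fixed = tuple(
        (i, settings.fixed_mods[aa])
        for i, aa in enumerate(sequence) if aa in settings.fixed_mods
    )
    cand = PeptideCandidate(sequence, ("x",), 0, 0, fixed)
    return np.sort([mz for _, _, mz in theoretical_fragments(cand)])


def _fragment_similar(a: str, b: str, settings: SearchSettings,
                      max_shared_fraction: float = 0.25) -> bool:
    """True when too many of a's b/y m/z values coincide with b's.

    A shuffled peptide keeps its base's composition (hence precursor mass)
    and often shares prefix/suffix fragment masses; a foreign spectrum built
    from such a shuffle still part-matches its base peptide in the database,
    which would bias false matches toward targets over decoys. Shuffles that
    stay fragment-similar to their base are therefore rejected.
    """
    fa, fb = _fragment_mzs(a, settings), _fragment_mzs(b, settings)
    tol = settings.product_tolerance_da
    idx = np.searchsorted(fb, fa)
    shared = 0
    for x, i in zip(fa, idx):
        left = abs(x - fb[i - 1]) <= tol if i > 0 else False
        right = abs(fb[i] - x) <= tol if i < len(fb) else False
        shared += left or right
    return shared > max_shared_fraction * len(fa)

def eligible_peptides(
    db: SearchDatabase, settings: SearchSettings | None = None
) -> dict[str, list[tuple[str, str]]]:
    """Informative tryptic peptides per origin: all REF peptides, SAV
    peptides covering the substituted residue, SJ peptides spanning the
    junction pair. Values are (sequence, accession), deduplicated."""
    settings = settings or SearchSettings()
    pools: dict[str, dict[str, str]] = {"REF": {}, "SAV": {}, "SJ": {}}
    for e in db.targets:
        for cand in digest_protein(e, settings):
            s, n = cand.start, len(cand.sequence)
            if e.origin == "SAV":
                pos = sav_variant_position(e)
                if not (s <= pos < s + n):
                    continue
            elif e.origin == "SJ":
                jl, jr = sj_junction_span(e)
                if not (s <= jl and jr < s + n):
                    continue
            pools[e.origin].setdefault(cand.sequence, e.accession)
    return {
        origin: sorted(seqs.items()) for origin, seqs in pools.items() if seqs
    }


def _make_spectrum(
    rng: np.random.Generator,
    scan_id: str,
    sequence: str,
    settings: SearchSettings,
    jitter_sd_da: float,
    frac_peaks_dropped: float,
    n_noise_peaks: int,
) -> tuple[Spectrum, int]:
    fixed = tuple(
        (i, settings.fixed_mods[aa])
        for i, aa in enumerate(sequence) if aa in settings.fixed_mods
    )
    cand = PeptideCandidate(sequence, ("synthetic",), 0, 0, fixed)
    mass = peptide_monoisotopic_mass(cand)
    z = int(rng.choice([2, 3]))
    frag_mz = np.array([mz for _, _, mz in theoretical_fragments(cand)])
    keep = rng.random(len(frag_mz)) >= frac_peaks_dropped
    if keep.sum() < 3:  # a spectrum needs some signal to be a spectrum
        keep[rng.choice(len(frag_mz), size=3, replace=False)] = True
    mz = frag_mz[keep] + rng.normal(0.0, jitter_sd_da, size=int(keep.sum()))
    intensity = rng.uniform(200.0, 1000.0, size=len(mz))
    if n_noise_peaks:
        mz = np.concatenate([mz, rng.uniform(150.0, 1500.0, size=n_noise_peaks)])
        intensity = np.concatenate(
            [intensity, rng.uniform(50.0, 400.0, size=n_noise_peaks)]
        )
    order = np.argsort(mz, kind="stable")
    spec = Spectrum(
        scan_id=scan_id,
        precursor_mz=(mass + z * PROTON) / z,
        precursor_charge=z,
        mz=mz[order],
        intensity=intensity[order],
    )
    return spec, z


def simulate_spectra(
    db: SearchDatabase,
    n_true: int = 200,
    n_noise: int = 100,
    jitter_sd_da: float = 0.005,
    frac_peaks_dropped: float = 0.2,
    n_noise_peaks: int = 30,
    seed: int = 0,
    settings: SearchSettings | None = None,
    origin_weights: Mapping[str, float] | None = None,
    scan_prefix: str = "scan",
    out_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[list[Spectrum], dict[str, dict]]:
    """Simulate MS/MS spectra for database peptides plus foreign spectra.

    True spectra are built from informative tryptic peptides of the target
    entries (b/y peaks with Gaussian m/z jitter, a fraction of fragment
    peaks dropped, uniform noise peaks added; precursor m/z exact at z in
    {2, 3}). Foreign spectra come from shuffled peptides verified absent
    from every target sequence — realistic precursor masses with no true
    answer, which is what calibrates the FDR. The returned manifest maps
    every scan to its generating peptide (origin 'foreign' for the
    shuffles).
    """
    settings = settings or SearchSettings()
    if jitter_sd_da >= settings.product_tolerance_da / 2:
        raise ValueError("fragment jitter must stay below half the product tolerance")
    rng = np.random.default_rng(seed)
    pools = eligible_peptides(db, settings)
    if not pools:
        raise ValueError("database yields no eligible peptides")
    origins = sorted(pools)
    if origin_weights:
        w = np.array([float(origin_weights.get(o, 0.0)) for o in origins])
    else:
        w = np.array([len(pools[o]) for o in origins], dtype=float)
    if w.sum() <= 0:
        raise ValueError("origin weights select no peptides")
    w = w / w.sum()

    blob = "|".join(e.sequence for e in db.targets)
    spectra: list[Spectrum] = []
    manifest: dict[str, dict] = {}

    for i in range(n_true):
        origin = origins[int(rng.choice(len(origins), p=w))]
        seq, acc = pools[origin][int(rng.integers(len(pools[origin])))]
        scan = f"{scan_prefix}_{i:05d}"
        spec, z = _make_spectrum(rng, scan, seq, settings, jitter_sd_da,
                                 frac_peaks_dropped, n_noise_peaks)
        spectra.append(spec)
        manifest[scan] = {"peptide": seq, "origin": origin, "charge": z,
                          "entry": acc}

    union = sorted({seq for pool in pools.values() for seq, _ in pool})
    for i in range(n_noise):
        scan = f"{scan_prefix}_{n_true + i:05d}"
        for _ in range(1000):
            base = union[int(rng.integers(len(union)))]
            letters = list(base)
            rng.shuffle(letters)
            foreign = "".join(letters)
            if (foreign != base and foreign not in blob
                    and not _fragment_similar(foreign, base, settings)):
                break
        else:
            raise RuntimeError("could not build a foreign peptide")
        spec, z = _make_spectrum(rng, scan, foreign, settings, jitter_sd_da,
                                 frac_peaks_dropped, n_noise_peaks)
        spectra.append(spec)
        manifest[scan] = {"peptide": foreign, "origin": "foreign", "charge": z,
                          "entry": None}

    if out_path is not None:
        write_mgf(spectra, out_path)
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))
    return spectra, manifest


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    records = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.scan_id,
                "pepmass": s.precursor_mz,
                **({"charge": s.precursor_charge} if s.precursor_charge else {}),
            },
        }
        for s in spectra
    ]
    _mgf.write(records, str(path), file_mode="w")
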