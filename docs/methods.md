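# Methods

This note documents the models, conventions and design choices behind
`proteoforge`, and what the synthetic validation does and does not show.

## Coordinates, strands and translation

All internal coordinates are 0-based half-open. GTF/GFF3 input (1-based
inclusive) and BED input (0-based half-open) are converted at the I/O
boundary, nowhere else. Minus-strand coding sequence is obtained by
concatenating the CDS intervals in genomic order and reverse-complementing
the concatenation as a single unit, so codons that straddle exon
boundaries are read correctly. Translation uses the standard nuclear
genetic code only — the inputs the pipeline consumes come from
poly-A-selected mRNA libraries, so mitochondrial codes are out of scope.
Codons containing any base other than A/C/G/T translate to `X`; peptides
containing `X` are excluded from digestion because their mass is
undefined.

## Database construction

**SAV entries.** A single-nucleotide variant is classified once per
overlapping transcript by substituting the (strand-complemented) alternate
base into the affected codon. Nonsynonymous effects emit the full-length
reference protein with the one substitution applied. Full-length entries —
rather than peptide-context windows — let the ordinary digestion machinery
produce every missed-cleavage peptide spanning the variant; the comparator
later enforces that a peptide only counts as a variant identification when
the substituted residue lies inside it. One substitution per entry: a
transcript carrying several variants yields several independent entries,
never combinatorial haplotypes, which mirrors single-variant records and
avoids exponential blow-up. Genotypes are ignored (any called alternate
allele produces an entry; the reference protein stays in the REF stream).
Stop-gain variants emit the truncated protein when it reaches the minimum
peptide length; stop-loss variants are skipped — the extension past the
lost stop is undefined without a 3'-sequence policy — and logged.

**SJ entries.** Junction identity is the exact intron interval
(chromosome, start, end), with strand compared only when both sides know
it; flank lengths and read counts never enter the comparison, and no
read-count threshold is applied (the 1 TPM rule governs transcript
records, not junction records). For each novel junction, up to 66 nt on
each side of the intron (capped by the BED block sizes, i.e. by the actual
read evidence) are spliced and translated in 3 frames — 6 when the strand
is unknown. 66 nt = 22 residues per side accommodates fully tryptic
peptides with two missed cleavages on either side of the junction. Each
translation is split at stops; a segment is kept when it spans the
junction with at least one residue on each side and reaches the engine's
minimum peptide length (shorter segments could never be identified). The
entry records the junction-residue pair's position so the comparator can
check that an identified peptide truly crosses the splice.

**Reduction.** Reference entries are dropped when their transcript's
abundance is strictly below 1 TPM; exactly 1.0 is retained. Transcripts
absent from the abundance table are treated as unquantified and excluded,
but reported rather than fatal. Reduction applies to the REF stream only —
SAV and SJ records are evidence-backed by construction. Reduction is
keyed on transcript-level TPM.

**Assembly and decoys.** Streams concatenate in REF, SAV, SJ order.
Within a stream, duplicate sequences collapse with merged provenance; a
SAV/SJ entry whose sequence equals a reference sequence is dropped (it
carries no new information). Decoys are full sequence reversals — one per
target, `DECOY_`-prefixed — which preserves the length distribution and
amino-acid composition of the target space exactly; peptide-level
redundancy between REF and full-length SAV entries is resolved at
PSM-to-protein mapping time, as search engines treat shared peptides.

## Search engine

Defaults (all configurable through `SearchSettings`, loadable from a YAML
file using the engine's own setting names): assumed precursor charges
2–4, 400 most intense peaks retained, trypsin without the proline rule,
≤ 2 missed cleavages, variable initiator methionine, carbamidomethyl-C
fixed (+57.02146 Da), oxidation-M variable (+15.99491 Da) with at most
1024 isoforms per peptide (enumerated in binary-counting order over sites,
truncation logged), ± 2.1 Da monoisotopic precursor tolerance with no
monoisotopic-peak correction, ± 0.025 Da product tolerance, 1% FDR cap.
Peptide length bounds default to 6–50 residues.

Scoring is the matched-fragment count plus the matched fraction of total
ion current. Matching is greedy nearest-peak with each observed peak
creditable to at most one theoretical fragment; equal-distance ties go to
the lower-m/z peak, and best-PSM ties prefer targets over decoys and then
the lexicographically smaller peptide — all purely for determinism.
Product ions are treated as singly charged b/y; true fragment-charge
deconvolution is a known limitation. The candidate index is a
sorted-by-mass array with binary search over the precursor window.

q-values: with one best PSM per spectrum, FDR(t) = D(t)/T(t) at each score
threshold (0 when no targets; ties counted together), and a PSM's q-value
is the minimum FDR over thresholds at or below its score, capped at 1.
The D/T convention (rather than 2D/(T+D)) follows the engine family this
design is modeled on.

Protein grouping is parsimonious: peptides map to every target containing
them as a substring, proteins with identical peptide sets merge, and
groups whose peptide set is a subset of another's are discarded, with
accession-order tie-breaks.

## Comparator

Peptide identity for all set comparisons is the bare sequence:
modifications are stripped, isoleucine and leucine stay distinct. (Mass
spectrometry cannot distinguish I/L; sequence databases do. This is a
recorded caveat, not a claim.) Classification precedence — reference
substring first, then SAV, then SJ — guarantees that nothing explainable
by the reference proteome is ever called novel. A peptide found only by
the SSdb that matches no reference protein, no variant record and no
junction record is an invariant breach and raises an error rather than
being silently binned.

## Synthetic data: what it emulates, and what it does not

The generator builds multi-exon genes on both strands whose exons are
whole numbers of codons (at least 22, so a 66-nt junction flank is never
truncated); CDS start with ATG and end with a stop, with no internal
stops. Exon skipping — joining the annotated donor of exon *i−1* to the
annotated acceptor of exon *i+1* — is the novel-junction mechanism because
it reuses annotated splice sites at a known frame, making the expected
junction peptide computable in closed form. Variants are placed with
their codon-level effect verified against the codon table at generation
time. Abundances are log-normal, rescaled by the k-th order statistic so
that exactly the stated fraction (default 30%) of transcripts falls
strictly below 1 TPM and one transcript sits exactly on the boundary,
making the boundary semantics observable.

Spectra are b/y ladders with Gaussian m/z jitter (default sd 0.005 Da,
well inside the ± 0.025 Da product tolerance), a dropped-peak fraction,
uniform noise peaks, and exact precursor m/z at charge 2 or 3. Foreign
spectra — the false-match population for FDR calibration — come from
shuffled database peptides verified absent from every target sequence.
A shuffle keeps its base's composition (hence precursor mass) and often
shares prefix/suffix fragment masses with it, which would bias its best
match toward the target side and corrupt the decoy-based FDR estimate, so
shuffles that keep more than 25% of their fragment m/z within tolerance
of the base peptide's are rejected and redrawn.

Not emulated: isotope envelopes, fragment charge > 1, retention time,
peak-intensity structure (intensities are uniform draws), chimeric
spectra, and real peptide detectability. Passing the end-to-end tests
therefore demonstrates the correctness of the machinery — coordinates,
translation, digestion, mass accounting, FDR estimation, classification —
under controlled conditions, not instrument-level performance on real
data.

## Validation studies and problem sizes

The validation protocol (tests and `scripts/acceptance.py`) uses: 100
random proteins (≤ 150 aa) for the digestion oracle; 1,000 random modified
peptides for the mass/fragment oracle (pyteomics as the independent
reference, agreement to 1e-4 Da); 1,000 random sequences for the
translation oracle (Biopython reference); a 20-gene sample with 10
nonsynonymous SNVs, 5 synonymous SNVs, 5 exon-skipping junctions and 30%
sub-1-TPM transcripts for loop closure; 200 true plus 100 foreign spectra
for end-to-end recovery and classification; 10 independent studies for
FDR calibration (mean empirical false-discovery proportion at the 1% cap).

The database-reduction study deserves its own note. The recovery effect —
identifications gained by searching a smaller, expression-restricted
database — emerges from decoy competition, which at desk scale is noisy.
The constructed demonstration uses a 300-gene reference with 10 expressed
genes (a 30× entry ratio), 150 high-quality spectra that anchor the score
distribution, and 300 minimal spectra (three surviving fragment peaks
among 600 noise peaks) whose true match is marginal. In the large
database, random decoy matches outscore marginal true matches often
enough to push the empirical FDR at their scores past 1%; in the reduced
database the same PSMs keep q-values at or below their large-database
values, and some peptides are identified only there. With these sizes the
effect reproduces across seeds; with materially smaller spectrum counts
the decoy counts in the relevant score region are 0–1 and the comparison
degenerates.

## Numerical conventions

Monoisotopic residue masses are standard values to five decimals; water =
18.010565 Da, proton = 1.007276 Da. Peak-filter ties keep the lower m/z.
All randomness in the generator flows from a single seeded NumPy
`Generator` per call; identical seeds give byte-identical FASTA, GTF,
VCF, BED, TSV, MGF and manifest outputs.
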