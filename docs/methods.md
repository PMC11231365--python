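# Methods

This note documents the models implemented in `scstrand`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Strand-inheritance model

Each chromosome of each cell inherits one template strand per homolog.
The generator assigns per-(cell, chromosome) states WW, CC or WC; with
`patterns="random"` the draw is WC : WW : CC = 2 : 1 : 1, matching
independent strand segregation of two homologs. For WC chromosomes the
haplotype→strand mapping is itself randomized per cell, which is exactly
the ambiguity the orientation-clustering step must resolve.

Reads from a homolog are emitted on its template strand, modified by
three mechanisms:

- **Sister-chromatid exchange (SCE).** Breakpoint count per homolog is
  Poisson(`sce_rate`/2) with uniform positions; the template strand flips
  downstream of each breakpoint. No empirical per-cell SCE rate is
  established for this protocol, so the default `sce_rate = 0.2` per
  chromosome ("a few per genome") is an arbitrary but documented choice.
- **Inversions.** Within an inversion interval carried by a haplotype,
  reads map to the opposite strand but identical reference coordinates
  (the aligned sequence is stored reference-oriented, as a BAM does).
  Reads straddling an inversion breakpoint are truncated at the
  breakpoint, emulating the clipping a real aligner would perform.
- **Background.** With probability `background_rate` a read is emitted on
  the wrong strand, modelling incomplete nascent-strand removal. Default
  0.01, consistent with sub-percent median backgrounds of good libraries.

Read lengths are lognormal with mean 2794 bp and sigma 0.45, giving a
length-weighted median (N50-like) near 3.1 kb. Base errors are uniform
substitutions (default 0.008, i.e. ~99.2% base accuracy); indel
sequencing errors and homopolymer-biased error profiles are *not*
simulated — real long-read error structure is harsher, so noise-robust
test results bound behavior under this error model only, not under
platform-specific artifacts. Reads carry their truth labels (cell,
coordinates, haplotype, strand, background flag) in structured read
names, which survive SAM round-trips.

The generator emits alignments directly from truth (coordinates plus a
CIGAR realizing the haplotype fragment: SNPs as substitutions, SVs as
D/I operations). Running an actual aligner is deliberately out of scope;
mapping ambiguity, soft-clipping and reference bias are therefore not
exercised by the tests.

## Demultiplexing

Template-orientation reads are laid out as
`bc2 + linker + insert + revcomp(linker) + revcomp(bc1)`; the
non-template strand is the reverse complement. Barcodes are matched
semi-globally (edlib, infix mode) in 200-bp end windows (capped at half
the read length); the best hit per barcode table is kept and hits with
Levenshtein distance > 5 are discarded. When two different barcodes tie
at the minimal distance the read is ambiguous — single-cell identity
must be unambiguous. A read is template iff the head carries a forward
2nd barcode and the tail a reverse 1st barcode (mirror layout for
non-template, which is then reverse-complemented). Barcode removal cuts
the matched span plus anything outside it at that end. The linker must
be found (distance ≤ 8) within 40 bp of both ends and is trimmed; a
second full-length scan finding a residual linker copy (either
orientation, distance ≤ 8) rejects the read as chimeric. Note that this
scan also rejects genuine reads whose genomic sequence happens to
resemble the linker within distance 8 — an inherent false-positive cost
of the rule that recurs for every read covering such a locus. Reads
whose head and tail barcodes imply different cells are treated as
ambiguous.

## Alignment processing

Unmapped, secondary, supplementary, mitochondrial (`chrM`/`MT`,
configurable) and MAPQ < 30 alignments are removed. PCR duplicates are
reads with identical cell, chromosome and strand whose start *and* end
coordinates differ by strictly less than 20 bp; duplicate groups are the
transitive closure of this pairwise relation (chained near-identical
molecules must collapse), computed with a sorted sweep + union-find in
O(n log n). The retained representative is the highest-MAPQ read (ties:
longest, then leftmost) — the relation itself never depends on the
representative choice, so marking is order-independent. Haplotype
annotation assigns a read to HP1/HP2 only when *every* informative
hetSNP allele it covers agrees with that haplotype; alleles matching
neither haplotype are uninformative. Base qualities are not thresholded.

## Cell QC

`background_chrom = min(N_crick, N_watson) / (N_crick + N_watson)`, and a
cell's background is the mean of its four smallest autosomal values
(sex chromosomes excluded). With few autosomes the statistic degrades:
a cell whose random states leave fewer than four single-strand
chromosomes gets WC values (~0.5) into its four minima. QC-oriented
synthetic runs therefore use ≥ 12 chromosomes; real karyotypes (22
autosomes) make this a non-issue. Retention requires
`unique_reads >= 80,000` and `background < 0.05` (strict, as printed;
the rodent preset lowers the read threshold to 70,000). Strand states:
CC if `P_c > 0.8`, WW if `P_c < 0.2`, WC if `0.35 <= P_c <= 0.65` (band
centered on 0.5, clear of both cutoffs; configurable), otherwise
unknown; chromosomes with fewer than 50 unique reads are always unknown
and excluded from phasing.

## Inversion detection

Per chromosome, CC cells (and WW cells with all read directions flipped)
form the composite pool. Each cell contributes only "pure" regions:
1-Mb bins (reads binned by midpoint, ≥ 10 reads per usable bin) whose
post-flip `P_c` is within 0.1 of the consensus profile. Consensus is the
per-bin median within the cell's profile cluster (average-linkage on
mean |ΔP_c|, cut at 0.15; clusters smaller than 3 fall back to the
global median). This excludes SCE-switched segments — which are
cell-specific — while keeping inversion bins, which deviate
consistently in *all* cells and therefore survive into the composite
where the scan can see them.

Candidates are maximal chains of Watson reads with inter-read gaps
≤ 5 kb ("continuous Watson coverage" needs an operational definition;
5 kb ≈ two read lengths). Chain termini are eroded while the outermost
read overlaps no other Watson read in the chain: an isolated flanking
read is background, and without erosion it drags non-inverted territory
(and its Crick reads) into the candidate, diluting P_w — the same
≥ 2-supporting-reads principle applied to interval boundaries.
Classification per candidate: < 20 total reads → filtered; `P_w > 0.9` →
HOM; `0.4 < P_w < 0.6` → HET; `P_w < 0.1` → filtered; otherwise
ungenotyped. The gaps between classes (0.1–0.4, 0.6–0.9) are preserved
as printed, not smoothed. Downstream contract: HOM intervals flip
variant phases, HET intervals exclude variants.

## Two-round haplotype phasing

**Anchors.** Pseudobulk pileup over all cells, duplicates included
(support, not complexity, is what matters for consensus). A site is an
anchor hetSNP when depth ≥ 10, the leading non-reference allele
fraction is in [0.25, 0.75], and a one-sided binomial test rejects the
5% error-rate null at α = 0.01. 10-kb bins with mean depth >
mean + 5 SD across bins form a high-coverage blacklist; reads and
anchors inside it are discarded. An external anchor VCF can replace the
internal caller.

**Orientation clustering.** For each WC cell the Crick and Watson
majority alleles at anchors form two vectors. For a cell pair,
`agree_parallel` counts Crick–Crick plus Watson–Watson matches,
`agree_antiparallel` the cross terms, and
`log2FC = log2((parallel + 1)/(antiparallel + 1))` (pseudocount 1 avoids
division by zero without changing the sign semantics). Edges feed a
parity union-find by decreasing |log2FC|; after local refinement, cells
whose weighted sign agreement is below 0.6 — e.g. contaminated or
state-miscalled cells — are excluded, as are cells disconnected from
the main component. WC chromosomes harboring an internal strand-state
switch (binned P_c leaving the 0.2–0.8 band) contribute only their
largest consistent segment, guarding round 1 against intra-chromosomal
SCEs.

**Consensus calling.** Crick reads of one cluster merge with Watson
reads of the other into haplotype read sets. Per site and haplotype the
consensus allele needs ≥ 2 supporting reads and ≥ 80% within-haplotype
agreement; a variant is emitted when both haplotypes pass and at least
one allele differs from the reference (hetSNP when they differ from
each other). Both thresholds are configurable.

**Round 2.** Every read from every cell — including WW/CC chromosomes
unusable in round 1 — is re-annotated against the round-1 phased
hetSNPs; unambiguous reads rebuild deeper haplotype read sets and
consensus calling repeats. Because round-2 assignment is allele-based,
not strand-based, it is immune to inversions and SCEs; inversion
corrections (swap phases in HOM intervals, drop variants in HET
intervals) are therefore applied to the round-1 set before round 2.

**Known-SNP linkage.** A known but unphased hetSNP is phased when each
haplotype's annotated reads give a unanimous allele with ≥ 2
observations and the two alleles are exactly {ref, alt}; any conflict
leaves it unphased.

**Evaluation.** Precision/recall compare (position, allele set) against
truth; genotype precision additionally requires the het/hom class. The
Hamming error rate is defined per chromosome as the mismatch fraction
among shared het sites minimized over the two labelings (chromosome-
scale phasing has exactly one label freedom per chromosome), aggregated
across chromosomes weighted by compared counts; per-chromosome values
are also reported since no canonical cross-chromosome aggregation
exists.

## SV calling and phasing

DEL/INS candidates are CIGAR operations ≥ 50 bp merged across reads when
positions agree within 500 bp and lengths within 25%; the candidate
takes the cluster median position/length. Blacklist rules: SVs within
1 kb of a neighbour (both members removed, breakpoint-to-breakpoint),
length > 10 kb, extreme coverage (< 10× or > 80× mean) in *all* provided
coverage tracks, and difficult/tandem annotation intervals longer than
200 bp; missing inputs skip their rule with a warning. Genotyping uses
the same signature match against each haplotype read set: support =
reads carrying the signature, oppose = reads spanning the locus with
50 bp flanks without it; HOM needs support ≥ 2 on both haplotypes,
HET-HPk needs support ≥ 2 on HPk and oppose ≥ 2 on the other
(`min_support = 2` mirrors the SNP rule). Heterozygous SVs inside HOM
inversions switch haplotype; SVs inside HET inversions are dropped,
applying the SNP exclusion rule uniformly. Nearest-hetSNP distances
(min over breakpoints) are bucketed ≤ 2 kb / 2–10 kb / > 10 kb.

## Contig clustering

The contig × cell matrix holds `(Crick − Watson)/(Crick + Watson)` from
filtered, duplicate-marked reads; contigs < 100 kb are dropped and
empty entries are masked (0 during clustering). Complete-linkage
agglomerative clustering (Euclidean, scikit-learn) of |matrix| rows
groups contigs by chromosome — |value| is invariant to assembly
orientation. Each cluster is re-clustered 2-way on signed rows; if the
two centroids do *not* anti-correlate the split is rejected and the
cluster stays single-orientation (a forced 2-way split would otherwise
fabricate orientations). Cluster sequences concatenate contigs (one
sub-cluster reverse-complemented) with 1-kb N gaps; the coordinate map
composes cluster → contig → reference (strand-aware, alleles
complemented on net-reverse lifts), and unliftable variants are
returned unmapped rather than guessed. `n_clusters` defaults to 30 for
human-scale assemblies; synthetic tests use the true chromosome count.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest scales at which every statistic is
well-powered: phasing runs use 2 chromosomes × 2 Mb at hetSNP rate
1e-3 with 40 cells × 720 reads (≈ 0.5× per cell, ≈ 20× pseudobulk);
inversion runs 2 × 5 Mb with twenty 100-kb events over 30 cells; SV
runs 1 × 2 Mb at sv rate 2e-5 over 10 cells (≈ 56× pooled); clustering
runs 24 × 125-kb contigs over 24 cells; demultiplexing 3 cells × 1000
reads. The acceptance script re-derives all per-run seeds from its
`--seed` argument, so every reported number is recomputed from scratch.

## Known limitations

- No aneuploidy handling: strand-state calls assume two homologs.
- Polyploid phasing is out of scope.
- The internal anchor caller is a binomial pileup test, adequate for the
  substitution-only error model; for real data an external caller's VCF
  can be supplied instead.
- Inversion calls are candidate-level; no automated false-positive
  curation is attempted, and nested or breakpoint-overlapping events are
  not modelled by the generator.
- The blacklist coverage rule generalizes "extreme in both supporting
  datasets" to "extreme in all provided tracks".
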