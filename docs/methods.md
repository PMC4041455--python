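# Methods

This note documents the models, conventions and numerical choices
behind `osseq`, and what the synthetic validation does and does not
demonstrate about real data.

## Coordinates and orientation

All internal coordinates are 0-based, half-open; conversion happens only
at file boundaries (VCF/SAM are 1-based on disk). A "+" probe's 40-mer
equals the forward reference at its anchor and polymerase extension
proceeds toward increasing coordinates; a "−" probe's 40-mer is the
reverse complement and extension proceeds toward decreasing coordinates.
The "terminal" 20-mer and 10-mer of the design gates are always the
extension-proximal end of the synthesized 40-mer. We adopt this reading
deliberately: the extension-proximal end drives both hybridization
specificity and priming, so the SNP-exclusion zone and the uniqueness
requirement protect that end. (Descriptions of the assay alternately
place the sensitive 10 bases at the "5′ side"; for the synthesized
oligo the 5′ end is the anchor-distal end, which would contradict the
stated rationale, so the extension end is used throughout and flagged
here.)

## k-mer mapability

The index stores exact both-strand occurrence counts of every k-window
(k ≤ 31, 2-bit packed). A k-mer and its reverse complement are two faces
of one physical site; palindromic k-mers count once per site. A position
is REPETITIVE when its window has more than one exact site, AMBIGUOUS
when the window contains N, UNIQUE_D1 when exactly one site exists and
no *other* site lies within `margin` substitutions on either strand, and
UNIQUE_STRICT when exact-unique but a near-miss exists. "Edit distance"
is interpreted as Hamming distance: descriptions of the filter use
"mismatches" and "edited bases" interchangeably, and the margin is kept
a parameter (default 1) because the stated tolerance ranges over one to
two mismatches. The margin test enumerates substitution neighbours
(3k per mismatch) against the hash index — linear in genome length,
adequate for the package's desk scale (synthetic genomes up to tens of
Mb); human-genome precomputation is out of scope. Probe gates accept
only UNIQUE_D1 terminal 20-mers.

`REPEAT_ADJACENT` is operationalised as any REPETITIVE k-mer window
overlapping the 20 bases immediately on the extension side of the
anchor; no published number exists for "immediately adjacent", and 20 b
protects the extension-proximal region.

## Probe placement

Placement windows: one flanking window per strand whose extension end
falls 100–200 b outside the target boundary, plus, for targets longer
than the 200 b tile spacing, windows every 200 b per strand with a ±60 b
tolerance ("approximately every 200 bases" is not given a tolerance; 60 b
is a parameter). Within a window the passing candidate closest to the
nominal anchor wins, ties toward the smaller coordinate, making catalogs
byte-deterministic. Unfillable windows produce DesignGap records rather
than exceptions. SNP targets get one probe per strand whose extension
crosses the SNP; breakpoint candidates get `probes_per_breakpoint`
(default 4) probes — half "+" upstream of the first coordinate, half "−"
downstream of the second, each side's 150–300 b distance range split
into one sub-window per slot, so every probe extends toward the
junction. The universal 61 bases (37 b read-2 primer region + 24 b
P7-lawn complement) ship as a configurable YAML file, not hard-coded.

## Capture QC conventions

Two distance rules coexist in the assay definition: reads within 1 kb of
the probe are on-target, and reads beyond a 1.5 kb insert are
off-target. Both are retained: ≤ 1 kb is on-target; (1 kb, 1.5 kb] is a
flagged gray zone, counted on-target only when requested; > 1.5 kb is
off-target. Default metrics use the 1 kb boundary. Probe assignment uses
a 20 b Read-2 prefix at ≤ 1 mismatch with unique-best-hit semantics
(ties unassigned); the catalog's terminal-20-mer uniqueness makes 20 b
sufficient, and full-40 matching is a flag. Mean base quality is the
arithmetic mean of Phred scores. ROI coverage uses probe anchors ± 50 b,
merged, counting only Read 1 bases from reads that do not overlap their
own probe's footprint, so synthetic sequence never inflates coverage.
The allele-fraction caller is a deliberate re-implementation of the
threshold behaviour (depth ≥ 10, fraction ≥ 0.15, mean quality ≥ 25)
without any statistical test; mixture detection rates are reported only
at sites with depth ≥ 100, following the convention for mixture
titrations.

## Local assembly and junction validation

k-mers (k = 19) are counted on both strands of the retained reads;
k-mers below an abundance floor (default = the coverage gate, 4) are
dropped before graph construction — the analogue of an assembler's
coverage cutoff — which removes sequencing-error branches. Contigs are
maximal non-branching paths, reported once in canonical orientation,
suppressed below 50 b length or mean k-mer coverage 4. These parameters
are honoured as contracts; bit-compatibility with any particular
assembler's internal coverage definition is not attempted.

Contig validation replaces a BLAST-style search with an exhaustive
breakpoint scan adequate at desk scale: every split of the contig into
prefix + suffix (each ≥ 20 b, echoing the anchor rule) is matched
exactly against both reference strands; the reference-contiguous split
is excluded. Junction coordinates are the read-direction end of the
prefix match and start of the suffix match. Microhomology makes the
split non-unique: equivalent representations (constant pos2 − pos1 for
deletion-type, constant pos2 + pos1 for inversion-type junctions) are
grouped, the smallest-pos1 representative is reported and the homology
length recorded. Somatic status is decided across samples: a junction is
somatic when present in a tumor and absent from every matched normal.
Inter-chromosomal junctions are representable even though the validated
synthetic set is intra-chromosomal.

## Synthetic data: what it emulates

Fragments are drawn uniformly with Normal(500 b, 60 b) lengths — the
500 b peak matches the library fragmentation target; the 60 b spread is
a package choice. A fragment is captured by a probe with that probe's
efficiency whenever it contains the 40 b anchor site (searched in both
orientations, so derived genomes with inversions behave correctly) and
has at least `min_read1_len` bases of extension room. Mean efficiency
defaults to 0.049 — the measured ~4.9% capture of eligible library
fragments — with per-probe lognormal spread (σ = 0.25, mean preserved)
to emulate probe-to-probe yield variation. Read 1 begins at the first
genomic base past the probe footprint and reads in the extension
direction; Read 2 is the probe 40-mer plus adjacent genomic sequence.
Errors are independent substitutions (default 10⁻³), qualities constant
Phred 35; no indel errors, PCR duplication or GC bias are modelled.
Truth SAM records come straight from provenance: a read maps iff its
source interval lifts contiguously to the reference.

A geometric consequence of the read model: reads from a probe placed
d bases from a SNP or junction only span it when Read 1 ≥ d + margin.
The mixture fixture therefore uses 250 b Read 1 (probes sit 100–200 b
from their SNP) and the SV fixture 350 b (probes sit 150–300 b from the
junction) — consistent with the empirical observation that target reads
align up to ~400 b from the probe — while panel QC keeps the 80×40
default. Fixture problem sizes (12 kb mixture genomes at ~90 k fragments
for per-site depth ≈ 200; 100 kb tumor genomes at 300 k fragments for
junction k-mer coverage well above the gate) are the package's chosen
desk-scale conditions.

Mixture truth uses two spike haplotypes at weight s/2 each, so
heterozygous spike-unique sites have expected allele fraction s/2 and
homozygous sites s. SV fixtures place junctions by rejection sampling so
that no single-base microhomology exists at the junction
(`junction_is_ambiguous`), making "exact coordinate recovery" well
posed; homology is still detected and reported when present. The
germline control is carried homozygously by the normal genome and by the
tumor's stromal fraction.

What passing tests show: the design gates, metrics, assembler and
validator are internally consistent, agree with independent brute-force
oracles, and recover planted truth under the stated read model. What
they do not show: performance on real flow-cell data — hybridization
thermodynamics, cross-hybridization of homologous gene families, index
hopping, cluster-formation losses and alignment artefacts are all
outside the simulator.

## Degenerate inputs and tie-breaks

Genomes shorter than k warn and yield empty indexes; non-ACGTN input is
rejected at construction. Uniqueness of a k-mer absent from the genome
is undefined and raises. Empty probe catalogs and empty yield vectors
raise; zero-depth pileup columns return allele fraction 0. The median
for uniformity includes zero-yield probes, so an all-zero pool scores
1.0 (every probe equals the median) — capture rate, not uniformity, is
the metric that exposes dead pools. Demultiplexing refuses tag tables
whose pairwise Hamming distance is ≤ 2·max_mismatch. All stochastic
components take explicit seeds and are byte-reproducible.
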