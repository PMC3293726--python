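# Methods

## Model and procedure

`utrsnp` treats marker discovery as a counting problem on read-vs-consensus
alignments. No genotype likelihoods or quality models are involved: the
data this targets (short pyrosequencing reads over de novo transcript
contigs, two to a few pooled cultivars) supports depth-based evidence
rules, and the whole pipeline is a deterministic function of the alignment.

**Coordinates.** Internal positions are 0-based half-open; SAM input is
converted on ingestion and every output surface (TSV, VCF, amplicon table)
is 1-based. Soft-clipped bases never align but do count toward read length
and end distance — the end-exclusion rule is about position *within the
read*, not within the alignment.

**Demultiplexing** is exact string matching of each barcode against the
read at a fixed offset, first match in table order wins, and barcode
uniqueness is enforced when the table is loaded so ties cannot arise.
Error-tolerant matching is deliberately out of scope; with the short MIDs
used in such libraries a 1-mismatch rule would collapse distinct barcodes.
The sample name is appended to the header after `_`, which is also the
convention the SAM reader uses to attribute samples.

**Pileup.** Every covered consensus position becomes a column of
observations `(read, sample, base, read_offset, end_distance)` where
`end_distance = min(read_offset, read_length−1−read_offset)`. Deletions
are GAP observations (no read base, no end distance); insertions go to a
side channel keyed by the preceding consensus position and never form
columns — only consensus positions are callable, and indels are excluded
from calling anyway.

**SNP filter cascade.** Per column, after dropping observations with
`end_distance < end_exclusion` and all N/GAP observations:

1. consensus allele = the FASTA base if it has any effective support, else
   the majority base (ties broken lexicographically). The consensus comes
   from the input FASTA rather than being recomputed, so results are
   reproducible against any assembler's output;
2. reject if total effective depth < `min_total_depth` (10);
3. reject if combined non-consensus fraction < `min_nonconsensus_frac`
   (0.20). The boundary is inclusive ("at least 20 %"), and the fraction is
   the *combined* non-consensus count, the same quantity a per-position
   variance report shows; an alternative reading (largest single
   non-consensus allele) would be strictly stricter;
4. alleles are the bases with ≥ `min_allele_reads` (3) effective reads;
   reject if fewer than `min_alleles` (2). Gaps never count as alleles;
5. sites with > 2 alleles are reported as multiallelic but excluded from
   the transition/transversion spectrum, which is defined on base pairs.

A single effective-count view drives *both* total depth and allele support
(i.e. depth is measured after end trimming). Whether the historical
depth-10 rule was applied before or after end trimming is ambiguous; one
uniform rule guarantees no call is supported by read ends anywhere.

**Statistics.** R = transitions/transversions, reported half-up to two
decimals; SNP density as round(total_bases/n_snps) bp-per-SNP and
half-up-2dp SNPs/kb. Half-up rounding matches how such tables are
conventionally printed (Python's default bankers' rounding would turn
0.125 into 0.12). Degenerate cases (no transversions, no SNPs) are
reported as absent rather than 0 or infinity.

**Haplotype linking.** Loci are linked when ≥ `min_span_reads` (3) reads
carry the *same* allele pair across both, with end exclusion and
allele-set restriction applied exactly as in calling. Blocks are connected
components of the link graph (linking is transitive; a read chain
A–B, B–C implies one region even if no read spans A–C), labelled A, B, C…
left-to-right per contig. Within a block:

1. each read covering ≥ 2 block loci yields a partial allele string;
2. identical partials with ≥ `min_span_reads` copies become segments;
3. segments merge when they overlap on ≥ 1 locus with identical alleles
   there and the merge partner is unique *in both directions* — if two
   different segments could extend the same overlap, neither merge happens,
   because inventing an unwitnessed recombinant is worse than reporting a
   gap;
4. loci a final string does not reach are written `?` (incomplete depth
   for a confirmed call);
5. strings indistinguishable after `?`-masking (one's defined loci a
   subset of a unique other's, agreeing everywhere) are folded together;
6. blocks with < 2 resulting haplotypes are dropped.

A haplotype's reported support is the number of read fragments consistent
with it and with no other reported haplotype, so block support totals never
exceed the number of distinct spanning reads. The historical analysis this
formalizes was performed visually; the segment-merge algorithm is a
faithful mechanization of "merge when differences are no longer traceable",
not a transcription of a recorded procedure.

**Amplicon targets.** Each SNP gets a ± `flank` (default 100 bp, truncated
at contig edges) consensus window with the focal site written `[X/Y]` and
every *other* called SNP in the window replaced by its IUPAC code — a
window sized so 50–100 bp amplicons fit anywhere inside it, with hidden
secondary polymorphism made visible to the assay designer (multiple SNPs in
one amplicon blur melt-curve discrimination).

## Synthetic data generator

The generator emulates the study conditions this pipeline targets: two
pooled samples (equimolar), reads with truncated-normal lengths of mean
85 bp (sd 10), mean coverage 20× per contig, SNP density 0.43/kb in
expectation, two haplotypes per contig at fraction 0.5, substitution error
rate 0 by default (indel errors available to exercise the exclusion
filter). Haplotype 1 *is* the consensus, so planted alt alleles are exactly
the haplotype-2 bases, mirroring an assembler collapsing to the majority
allele.

Planted SNPs are drawn Poisson at the configured rate and grouped into
blocks of 1–3 loci spaced 10–40 bp apart — close enough for single reads to
span neighbouring loci. Two placement rules are design choices, not
emergent properties: blocks sit at least one mean read length from contig
edges (uniform read starts leave ends undercovered, and marker design
avoids contig edges regardless), and successive blocks are separated by
more than the maximum read length so planted blocks are unambiguously
distinct linkage regions.

What the generator does **not** model: 454 homopolymer flow noise,
expression-level variation in coverage (reads are uniform along contigs),
poly-A mispriming artifacts, chimeric reads, and assembly error (the truth
SAM places every read at its generating interval). Passing recovery tests
therefore demonstrates the correctness of the counting and linking logic
under clean alignments, not robustness to misassembly or alignment error.

Even with zero sequencing error, haplotype-block recovery is not guaranteed
at every seed: the minor haplotype may get only 2 reads spanning some locus
pair, below the 3-spanning-read rule, in which case the block is dropped or
reported with `?` — by design, and matching the behaviour of the rule on
real data.

## Numerical and design choices

- Flank length in the SNP report: 50 bp per side (truncated at edges) —
  enough context to re-identify the locus in other germplasm.
- Tie-breaks: consensus-fallback majority vote breaks count ties
  lexicographically; allele lists sort by descending count then base;
  haplotypes by descending support then string.
- Sub-threshold link pairs are retained on edges for inspection but never
  create edges or haplotypes.
- The VCF writer verifies REF against the contig FASTA and refuses to write
  on mismatch (self-consistency gate); conformance is tested against an
  independent parser.
- Barcodes of unequal length are allowed; matching is per-barcode exact
  comparison at the configured offset.
- FASTA ambiguity codes other than N are normalized to N on input; U maps
  to T.

## Problem sizes in tests

The bundled suites run on deliberately small instances: the shared recovery
dataset is 20 contigs × 2 kb at depth 20 (~9,400 reads), oracle-equivalence
suites use 200 random instances of ≤ 60 bp contigs with ≤ 40 noisy reads,
and property sweeps use 30 instances. These sizes make the full suite and
the acceptance script each complete in well under a minute while still
exercising every filter boundary; the implementation itself streams reads
and scales linearly in total aligned bases.

## Known limitations

- Pairwise locus linking is O(k²) per contig in the number of called loci —
  irrelevant for transcript contigs (a handful of SNPs each), inappropriate
  for megabase chromosomes.
- No base- or mapping-quality awareness; evidence is read counts only.
- Haplotype enumeration assumes the locus set is small (it enumerates
  segments, not an MEC optimization); statistical phasing across
  individuals is out of scope.
- The simulator's two-haplotype model cannot represent >2 alleles per
  locus, so multiallelic handling is tested via hand-built pileups instead.
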