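# utrsnp

Reference-free discovery of gene-linked SNP and haplotype markers from
barcoded 3'UTR-style transcriptome reads aligned to de novo assembled
contigs.

## The problem

Non-model crops often have no reference genome, yet breeding programs need
gene-linked markers. One practical route is reduced-representation RNA
sequencing of the 3'UTR: pool barcoded cDNA libraries from a few cultivars,
sequence short single-end reads (historically 454 pyrosequencing, mean
~85 bp), assemble them de novo into consensus contigs, and mine the
read-vs-consensus alignments for polymorphism. Because every contig is
transcript-derived, every marker is physically linked to a gene —
immediately useful for gene-assisted breeding, genotyping and population
studies.

`utrsnp` implements the computational half of that workflow. Assembly is
consumed as input (contig FASTA + read-to-contig SAM); the package provides:

- **demux** — strip in-line barcodes (MIDs) at a configurable offset and
  label each read header with its sample (`..._<sample>`);
- **pileup** — per-contig, per-position base observations that retain read
  identity, sample and distance from the read ends;
- **snp_caller** — the filter cascade: minimum total effective depth 10,
  combined non-consensus fraction ≥ 20 %, at least two alleles each backed
  by ≥ 3 reads, bases within 5 bp of a read end discarded, indels excluded;
- **haplotyper** — read-backed linking: two SNP loci join a haplotype block
  when ≥ 3 reads carry one allele pair across both; blocks are transitive
  closures, haplotype allele strings are assembled from read-supported
  segments, and loci a string cannot reach are written `?`;
- **reports** — SNP report TSV with flanking sequence and `[X/Y]`
  polymorphism notation, haplotype table, VCFv4.2, amplicon-target FASTA
  for 50–100 bp melt-assay (HRM) design with neighbouring SNPs masked as
  IUPAC codes, plus JSON/text run summaries;
- **simulate** — a seeded generator planting diploid haplotypes on random
  contigs and drawing 454-like reads, with truth tables so the entire
  pipeline can be scored for recovery.

Summary statistics follow the field's conventions: the transition /
transversion ratio R = (C↔T + A↔G) / (A↔C + A↔T + C↔G + G↔T), and SNP
density as both bp-per-SNP and SNPs per kb of assembled gene space.

## Worked example

Simulate a small planted dataset, then run the full pipeline:

```sh
utrsnp simulate --n-contigs 6 --depth 20 --seed 4 --out-dir sim/
utrsnp run \
  --reads sim/reads_multiplexed.fasta --barcodes sim/barcodes.csv \
  --contigs sim/contigs.fasta --aln sim/truth.sam \
  --out-dir out/ --deterministic
cat out/snp_stats.json
```

which prints (this exact run):

```json
{
  "n_snps": 5,
  "transitions_by_pair": {"C/T": 1, "A/G": 0},
  "transversions_by_pair": {"A/C": 3, "A/T": 0, "C/G": 0, "G/T": 1},
  "ts_total": 1,
  "tv_total": 4,
  "r_value": 0.25,
  "total_bases": 12409,
  "snps_per_kb": 0.4,
  "bp_per_snp": 2482
}
```

Five SNPs passed the cascade on 12,409 bases of simulated contig space
(0.4 SNPs/kb — a handful of planted sites, so the spectrum is noisy);
`out/snps.tsv` lists each site with its flanks and `[X/Y]` polymorphism,
`out/haplotypes.tsv` the read-backed allele strings per block, and
`out/amplicon_targets.fasta` assay-ready windows. With the truth tables in
`sim/` you can confirm every called site is planted and vice versa — the
test suite does exactly that.

Every stage is also a library function (`utrsnp.call_snps`,
`utrsnp.phase`, ...) operating on plain in-memory objects.

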