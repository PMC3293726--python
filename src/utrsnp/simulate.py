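"""Synthetic data generator: contigs with planted diploid haplotypes and
pyrosequencing-style reads, plus truth tables for recovery scoring.

The generator emulates the substrate the pipeline is built for: short
(mean ~85 bp) single-end reads from a pooled multi-sample 3'UTR library,
aligned to de novo consensus contigs.  Each contig carries two haplotypes;
haplotype 1 IS the consensus sequence (mirroring an assembler collapsing to
the majority allele), haplotype 2 differs at the planted SNP positions, so
the planted alt alleles are exactly the haplotype-2 bases.  Variants are
planted in clustered blocks whose intra-block spacing is small enough for
single reads to span neighbouring loci, and blocks are separated by more
than a read length so that distinct planted blocks stay unlinked.

All randomness flows through one seeded numpy generator; identical configs
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .haplotyper import HaplotypeBlock
from .io_formats import ContigSet
from .snp_caller import SnpCall

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    n_contigs: int = 20
    contig_length_range: tuple[int, int] = (1500, 2500)
    samples: tuple[str, ...] = ("Bing", "Rainier")
    barcodes: tuple[str, ...] = ("ATAGTGA", "ATGCATG")
    barcode_offset: int = 0
    ploidy_haplotypes: int = 2
    snp_rate_per_kb: float = 0.43
    #: planted SNPs per block (inclusive range) and spacing between
    #: neighbouring loci within a block, in bases
    snps_per_block: tuple[int, int] = (1, 3)
    block_spacing: tuple[int, int] = (10, 40)
    minor_haplotype_fraction: float = 0.5
    depth: float = 20.0  # mean reads per base
    read_length_mean: float = 85.0
    read_length_sd: float = 10.0
    substitution_error_rate: float = 0.0
    indel_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.minor_haplotype_fraction <= 1.0:
            raise ValueError("minor_haplotype_fraction must be in [0, 1]")
        for rate in (self.substitution_error_rate, self.indel_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.ploidy_haplotypes != 2:
            raise ValueError("only diploid (2-haplotype) simulation is supported")
        if len(self.samples) != len(self.barcodes):
            raise ValueError("need one barcode per sample")
        longest = max(len(b) for b in self.barcodes)
        if self.read_length_mean <= self.barcode_offset + longest:
            raise ValueError("read_length_mean must exceed barcode_offset + barcode length")

    @property
    def max_read_length(self) -> int:
        return int(self.read_length_mean + 4 * self.read_length_sd)


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    sample: str
    contig_id: str
    start: int  # 0-based on the contig
    end: int  # half-open
    haplotype: int  # 1 or 2


@dataclass
class SimTruth:
    config: SimConfig
    contigs: ContigSet  # consensus = haplotype 1
    variants: list[tuple[str, int, str, str]]  # (contig, 0-based pos, ref, alt)
    #: planted blocks: contig -> list of sorted position lists
    blocks: dict[str, list[list[int]]]
    #: contig -> (haplotype-1 sequence, haplotype-2 sequence)
    haplotypes: dict[str, tuple[str, str]]

    def variant_positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self.variants}

    def block_allele_strings(self, contig_id: str, positions: Sequence[int]) -> tuple[str, str]:
        h1, h2 = self.haplotypes[contig_id]
        return (
            "".join(h1[p] for p in positions),
            "".join(h2[p] for p in positions),
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant_blocks(
    rng: np.random.Generator, length: int, cfg: SimConfig
) -> list[list[int]]:
    """Draw clustered SNP positions for one contig.

    The expected total count matches ``snp_rate_per_kb`` over the full
    contig; blocks are confined to the interior (one mean read length from
    each edge, where simulated coverage is thin) and separated by more than
    the maximum read length.
    """
    margin = int(round(cfg.read_length_mean))
    min_gap = cfg.max_read_length + 20
    lo, hi = margin, length - margin
    n_target = rng.poisson(cfg.snp_rate_per_kb * length / 1000.0)
    if n_target == 0 or hi - lo < 1:
        return []
    sizes: list[int] = []
    remaining = n_target
    while remaining > 0:
        k = int(rng.integers(cfg.snps_per_block[0], cfg.snps_per_block[1] + 1))
        sizes.append(min(k, remaining))
        remaining -= sizes[-1]
    placed: list[list[int]] = []
    occupied: list[tuple[int, int]] = []
    for k in sizes:
        spacings = [int(rng.integers(cfg.block_spacing[0], cfg.block_spacing[1] + 1)) for _ in range(k - 1)]
        span = sum(spacings)
        if hi - lo <= span:
            continue
        for _ in range(200):
            start = int(rng.integers(lo, hi - span))
            if all(start - min_gap >= e or start + span + min_gap <= s for s, e in occupied):
                positions = [start]
                for sp in spacings:
                    positions.append(positions[-1] + sp)
                placed.append(positions)
                occupied.append((start, start + span))
                break
    placed.sort(key=lambda b: b[0])
    return placed


def simulate_truth(cfg: SimConfig = SimConfig()) -> SimTruth:
    """Generate contigs, planted variants and the two haplotype sequences."""
    rng = np.random.default_rng([cfg.seed, 0])
    contigs = ContigSet()
    variants: list[tuple[str, int, str, str]] = []
    blocks: dict[str, list[list[int]]] = {}
    haplotypes: dict[str, tuple[str, str]] = {}
    for i in range(cfg.n_contigs):
        cid = f"contig{i + 1:04d}"
        length = int(rng.integers(cfg.contig_length_range[0], cfg.contig_length_range[1] + 1))
        h1 = _random_seq(rng, length)
        contig_blocks = _plant_blocks(rng, length, cfg)
        h2_chars = list(h1)
        for block in contig_blocks:
            for pos in block:
                ref = h1[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                h2_chars[pos] = alt
                variants.append((cid, pos, ref, alt))
        contigs.add(cid, h1)
        blocks[cid] = contig_blocks
        haplotypes[cid] = (h1, "".join(h2_chars))
    return SimTruth(cfg, contigs, variants, blocks, haplotypes)


@dataclass
class SimRead:
    read_id: str
    sample: str
    contig_id: str
    start: int
    cigar: list[tuple[int, int]]  # pysam op codes
    seq: str


@dataclass
class SimReadSet:
    truth: SimTruth
    reads: list[SimRead] = field(default_factory=list)
    provenance: list[ReadProvenance] = field(default_factory=list)

    def write_reads_fasta(self, path: str | Path) -> None:
        """Demultiplexed-style reads: sample name suffixed to the id."""
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f">{r.read_id}_{r.sample}\n{r.seq}\n")

    def write_multiplexed_fasta(self, path: str | Path) -> None:
        """Pooled library form: offset filler + sample barcode + read."""
        cfg = self.truth.config
        rng = np.random.default_rng([cfg.seed, 2])
        barcode_of = dict(zip(cfg.samples, cfg.barcodes))
        with open(path, "w") as fh:
            for r in self.reads:
                filler = _random_seq(rng, cfg.barcode_offset)
                fh.write(f">{r.read_id}\n{filler}{barcode_of[r.sample]}{r.seq}\n")

    def write_truth_sam(self, path: str | Path) -> None:
        contigs = self.truth.contigs
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in contigs.items()],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            tid = {cid: i for i, cid in enumerate(contigs)}
            for r in self.reads:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = f"{r.read_id}_{r.sample}"
                a.flag = 0
                a.reference_id = tid[r.contig_id]
                a.reference_start = r.start
                a.mapping_quality = 60
                a.cigartuples = r.cigar
                a.query_sequence = r.seq
                sam.write(a)

    def write_truth_tables(self, variants_path: str | Path, haplotypes_path: str | Path) -> None:
        truth = self.truth
        with open(variants_path, "w") as fh:
            fh.write("contig\tposition\tref\talt\n")
            for cid, pos, ref, alt in truth.variants:
                fh.write(f"{cid}\t{pos + 1}\t{ref}\t{alt}\n")
        with open(haplotypes_path, "w") as fh:
            fh.write("contig\tblock\tpositions\thaplotype1\thaplotype2\n")
            for cid in truth.contigs:
                for i, block in enumerate(truth.blocks.get(cid, [])):
                    h1, h2 = truth.block_allele_strings(cid, block)
                    positions = ",".join(str(p + 1) for p in block)
                    fh.write(f"{cid}\t{i + 1}\t{positions}\t{h1}\t{h2}\n")


def _apply_errors(
    rng: np.random.Generator, seq: str, cfg: SimConfig
) -> tuple[str, list[tuple[int, int]]]:
    """Inject substitution (and optionally single-base indel) errors; returns
    the mutated sequence and its CIGAR against the error-free template."""
    out: list[str] = []
    cigar: list[tuple[int, int]] = []

    def emit(op: int, n: int = 1) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    for base in seq:
        if cfg.indel_error_rate > 0 and rng.random() < cfg.indel_error_rate:
            if rng.random() < 0.5:
                emit(2)  # deletion: template base skipped
                continue
            out.append(str(rng.choice(list("ACGT"))))
            emit(1)  # insertion before the template base
        if cfg.substitution_error_rate > 0 and rng.random() < cfg.substitution_error_rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        else:
            out.append(base)
        emit(0)
    return "".join(out), cigar


def simulate_reads(truth: SimTruth, cfg: SimConfig | None = None) -> SimReadSet:
    """Draw reads uniformly along each contig's haplotypes.

    Per-contig read count is depth * length / mean read length; lengths are
    truncated-normal; the haplotype is chosen per read with probability
    ``minor_haplotype_fraction`` for haplotype 2; the sample label is
    uniform over configured samples (an equimolar pool).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    out = SimReadSet(truth)
    counter = 0
    for cid in truth.contigs:
        h1, h2 = truth.haplotypes[cid]
        clen = len(h1)
        n_reads = max(1, int(round(cfg.depth * clen / cfg.read_length_mean)))
        for _ in range(n_reads):
            sample = cfg.samples[int(rng.integers(len(cfg.samples)))]
            hap = 2 if rng.random() < cfg.minor_haplotype_fraction else 1
            for _ in range(100):
                length = int(np.clip(rng.normal(cfg.read_length_mean, cfg.read_length_sd), 20, cfg.max_read_length))
                if length <= clen:
                    break
            else:
                length = clen
            start = int(rng.integers(0, clen - length + 1))
            template = (h2 if hap == 2 else h1)[start : start + length]
            seq, cigar = _apply_errors(rng, template, cfg)
            counter += 1
            rid = f"r{counter:06d}"
            out.reads.append(SimRead(rid, sample, cid, start, cigar, seq))
            out.provenance.append(ReadProvenance(rid, sample, cid, start, start + length, hap))
    return out


def write_all(readset: SimReadSet, out_dir: str | Path) -> dict[str, Path]:
    """Write the full simulator output bundle into *out_dir*."""
    from .io_formats import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": out_dir / "contigs.fasta",
        "reads": out_dir / "reads.fasta",
        "multiplexed": out_dir / "reads_multiplexed.fasta",
        "sam": out_dir / "truth.sam",
        "variants": out_dir / "truth_variants.tsv",
        "haplotypes": out_dir / "truth_haplotypes.tsv",
        "barcodes": out_dir / "barcodes.csv",
    }
    write_fasta(readset.truth.contigs, paths["contigs"])
    readset.write_reads_fasta(paths["reads"])
    readset.write_multiplexed_fasta(paths["multiplexed"])
    readset.write_truth_sam(paths["sam"])
    readset.write_truth_tables(paths["variants"], paths["haplotypes"])
    cfg = readset.truth.config
    with open(paths["barcodes"], "w") as fh:
        for sample, barcode in zip(cfg.samples, cfg.barcodes):
            fh.write(f"{sample},{barcode}\n")
    return paths


def score_snp_calls(
    truth: SimTruth, snps: Sequence[SnpCall]
) -> tuple[float | None, float | None]:
    """(precision, recall) of called sites against planted variants.

    A call is a true positive when its position is planted and its allele
    set equals {ref, alt}.  Returns None components when undefined (no
    calls / no planted variants).
    """
    planted = {(c, p): (ref, alt) for c, p, ref, alt in truth.variants}
    tp = 0
    for s in snps:
        expected = planted.get((s.contig_id, s.pos))
        if expected is not None and set(s.allele_bases) == set(expected):
            tp += 1
    precision = tp / len(snps) if snps else None
    recall = tp / len(planted) if planted else None
    return precision, recall


def score_haplotype_blocks(
    truth: SimTruth, blocks: Sequence[HaplotypeBlock]
) -> tuple[float | None, int]:
    """Fraction of planted multi-SNP blocks recovered exactly.

    A planted block is recovered when a reported block on the same contig
    has exactly its positions and its haplotype strings are exactly the two
    planted allele strings (no '?').  Returns (fraction, n_truth_blocks);
    fraction is None when nothing multi-SNP was planted.
    """
    reported: dict[tuple[str, tuple[int, ...]], set[str]] = {}
    for b in blocks:
        reported[(b.contig_id, b.positions)] = {h.allele_string for h in b.haplotypes}
    n_truth = 0
    recovered = 0
    for cid, contig_blocks in truth.blocks.items():
        for positions in contig_blocks:
            if len(positions) < 2:
                continue
            n_truth += 1
            expected = set(truth.block_allele_strings(cid, positions))
            if reported.get((cid, tuple(positions))) == expected:
                recovered += 1
    return (recovered / n_truth if n_truth else None), n_truth
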