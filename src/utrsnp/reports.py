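"""Marker deliverables: SNP report TSV, haplotype table, VCF, amplicon
targets for melt-assay design, and run summaries.

All report coordinates are 1-based.  TSVs are tab-delimited UTF-8 with a
single header row and deterministic row order (contig id, then position).
The polymorphism column uses the ``[X/Y]`` notation with alleles in
descending support order.
"""

from __future__ import annotations

import json
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .haplotyper import HaplotypeBlock
from .io_formats import AlignedRead, ContigSet
from .snp_caller import SnpCall, round_half_up

_BASES = ("A", "C", "G", "T")

IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def percent_of(part: int | float, whole: int | float, digits: int = 1) -> float:
    """part/whole as a percentage, half-up rounded to ``digits`` decimals."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round_half_up(100.0 * part / whole, digits)


def polymorphism_notation(snp: SnpCall) -> str:
    return "[" + "/".join(b for b, _, _ in snp.alleles) + "]"


def _sample_counts_str(snp: SnpCall) -> str:
    parts = []
    for base, _, per_sample in snp.alleles:
        inner = ",".join(f"{s or 'unlabeled'}={c}" for s, c in sorted(per_sample.items()))
        parts.append(f"{base}:{inner}")
    return ";".join(parts)


def write_snp_report(snps: Sequence[SnpCall], path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """One row per SNP: contig, 1-based position, consensus, effective depth,
    per-base counts, allele list, per-sample allele counts, 5' flank,
    polymorphism as [X/Y], 3' flank."""
    cols = [
        "contig", "position", "consensus", "depth",
        "count_A", "count_C", "count_G", "count_T",
        "alleles", "sample_counts", "flank_5p", "polymorphism", "flank_3p",
    ]
    ordered = sorted(snps, key=lambda s: (s.contig_id, s.pos))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for s in ordered:
            alleles = ";".join(f"{b}:{c}" for b, c, _ in s.alleles)
            row = [
                s.contig_id, str(s.pos + 1), s.consensus_base, str(s.total_effective_depth),
                *(str(s.base_counts.get(b, 0)) for b in _BASES),
                alleles, _sample_counts_str(s), s.flank5, polymorphism_notation(s), s.flank3,
            ]
            fh.write("\t".join(row) + "\n")


def read_snp_report(path: str | Path) -> list[SnpCall]:
    """Reload a SNP report written by :func:`write_snp_report`.

    Per-sample detail beyond the allele rows is reconstructed from the
    sample_counts column; substitution class is recomputed from the alleles.
    """
    from .snp_caller import MULTIALLELIC, classify_substitution

    calls: list[SnpCall] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                continue
            rec = dict(zip(header, fields))
            sample_counts: dict[str, Counter] = {}
            if rec["sample_counts"]:
                for part in rec["sample_counts"].split(";"):
                    base, _, inner = part.partition(":")
                    ctr: Counter = Counter()
                    for kv in inner.split(","):
                        name, _, c = kv.rpartition("=")
                        ctr["" if name == "unlabeled" else name] = int(c)
                    sample_counts[base] = ctr
            alleles = []
            for part in rec["alleles"].split(";"):
                base, _, c = part.partition(":")
                alleles.append((base, int(c), sample_counts.get(base, Counter())))
            sub = (
                classify_substitution(alleles[0][0], alleles[1][0])
                if len(alleles) == 2
                else MULTIALLELIC
            )
            calls.append(
                SnpCall(
                    contig_id=rec["contig"],
                    pos=int(rec["position"]) - 1,
                    consensus_base=rec["consensus"],
                    alleles=alleles,
                    total_effective_depth=int(rec["depth"]),
                    substitution_class=sub,
                    flank5=rec["flank_5p"],
                    flank3=rec["flank_3p"],
                    base_counts={b: int(rec[f"count_{b}"]) for b in _BASES if int(rec[f"count_{b}"])},
                    sample_counts=sample_counts,
                )
            )
    return calls


def write_haplotype_report(blocks: Sequence[HaplotypeBlock], path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """One row per haplotype: contig, region label, 1-based positions,
    allele string (with '?' for incomplete depth), read support, per-sample
    support."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("contig\tregion\tpositions\thaplotype\tread_support\tsample_support\n")
        for blk in sorted(blocks, key=lambda b: (b.contig_id, b.positions[0])):
            positions = ",".join(str(p + 1) for p in blk.positions)
            for hap in blk.haplotypes:
                per_sample = ";".join(
                    f"{s or 'unlabeled'}={c}" for s, c in sorted(hap.per_sample_support.items())
                )
                fh.write(
                    f"{blk.contig_id}\t{blk.region_label}\t{positions}\t"
                    f"{hap.allele_string}\t{hap.read_support}\t{per_sample}\n"
                )


def write_vcf(
    snps: Sequence[SnpCall],
    contigs: ContigSet,
    path: str | Path,
    samples: Sequence[str] | None = None,
    source: str = "utrsnp",
) -> None:
    """Write calls as VCFv4.2.

    REF is the consensus base (verified against the contig FASTA — a
    mismatch is a hard error), ALT the remaining alleles in descending
    support order.  INFO carries the effective depth (DP); per-sample
    columns carry AD-style allele-supporting read counts over REF+ALT.
    """
    if samples is None:
        seen: set[str] = set()
        for s in snps:
            for ctr in s.sample_counts.values():
                seen.update(k for k in ctr if k)
        samples = sorted(seen) if seen else ["pooled"]
    ordered = sorted(snps, key=lambda s: (s.contig_id, s.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for cid, seq in contigs.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Effective read depth after end exclusion">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele-supporting read counts">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for s in ordered:
            ref = s.consensus_base
            fasta_base = contigs[s.contig_id][s.pos]
            if fasta_base not in ("N",) and ref != fasta_base:
                raise ValueError(
                    f"REF {ref!r} at {s.contig_id}:{s.pos + 1} does not match contig FASTA base {fasta_base!r}"
                )
            alts = [b for b, _, _ in s.alleles if b != ref]
            if not alts:
                continue
            alleles = [ref] + alts
            cols = []
            for sample in samples:
                ad = []
                for base in alleles:
                    ctr = s.sample_counts.get(base, Counter())
                    if sample == "pooled":
                        ad.append(sum(ctr.values()))
                    else:
                        ad.append(ctr.get(sample, 0))
                cols.append(",".join(str(c) for c in ad))
            fh.write(
                f"{s.contig_id}\t{s.pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t"
                f"DP={s.total_effective_depth}\tAD\t" + "\t".join(cols) + "\n"
            )


@dataclass
class AmpliconTarget:
    contig_id: str
    snp_pos: int  # 1-based
    target_sequence: str  # consensus window with the SNP as [X/Y]
    window_start: int  # 1-based inclusive
    window_end: int  # 1-based inclusive
    other_snps_masked: int


def extract_amplicon_targets(
    snps: Sequence[SnpCall],
    consensus: ContigSet,
    flank: int = 100,
) -> list[AmpliconTarget]:
    """Windows around each SNP for short-amplicon (50-100 bp) assay design.

    The target SNP is written ``[X/Y]``; any OTHER called SNP falling inside
    the window is replaced by its IUPAC ambiguity code so the designer can
    avoid placing primers (or interpreting melt curves) over it — multiple
    polymorphisms in one amplicon confound genotype discrimination.
    """
    by_contig: dict[str, list[SnpCall]] = {}
    for s in snps:
        by_contig.setdefault(s.contig_id, []).append(s)
    targets: list[AmpliconTarget] = []
    for s in sorted(snps, key=lambda x: (x.contig_id, x.pos)):
        seq = consensus[s.contig_id]
        lo = max(0, s.pos - flank)
        hi = min(len(seq), s.pos + flank + 1)  # 0-based half-open
        chars = list(seq[lo:hi])
        masked = 0
        for other in by_contig[s.contig_id]:
            if other.pos == s.pos or not (lo <= other.pos < hi):
                continue
            bases = frozenset(other.allele_bases)
            chars[other.pos - lo] = IUPAC.get(bases, "N")
            masked += 1
        chars[s.pos - lo] = polymorphism_notation(s)
        targets.append(
            AmpliconTarget(
                contig_id=s.contig_id,
                snp_pos=s.pos + 1,
                target_sequence="".join(chars),
                window_start=lo + 1,
                window_end=hi,
                other_snps_masked=masked,
            )
        )
    return targets


def write_amplicon_targets(
    targets: Sequence[AmpliconTarget], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    with open(fasta_path, "w") as fh:
        for t in targets:
            fh.write(f">{t.contig_id}_snp{t.snp_pos}\n{t.target_sequence}\n")
    with open(tsv_path, "w") as fh:
        fh.write("contig\tsnp_position\twindow_start\twindow_end\tother_snps_masked\n")
        for t in targets:
            fh.write(
                f"{t.contig_id}\t{t.snp_pos}\t{t.window_start}\t{t.window_end}\t{t.other_snps_masked}\n"
            )


@dataclass
class RunSummary:
    n_reads: int
    per_sample_reads: dict[str, int]
    mean_read_length: int | None
    n_contigs: int
    mean_contig_length: int | None
    median_contig_length: float | None
    total_contig_bases: int
    n_snps: int
    n_snp_contigs: int
    n_haplotypes: int
    n_blocks: int
    n_block_contigs: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def pretty(self) -> str:
        d = self.as_dict()
        width = max(len(k) for k in d)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in d.items())


def summarize_run(
    reads: Iterable[AlignedRead] | None,
    contigs: ContigSet,
    snps: Sequence[SnpCall],
    blocks: Sequence[HaplotypeBlock],
) -> RunSummary:
    """Headline counts for a run; mean lengths rounded to integers as a
    sequencing summary table would print them."""
    n_reads = 0
    per_sample: Counter = Counter()
    lengths: list[int] = []
    if reads is not None:
        for r in reads:
            n_reads += 1
            per_sample[r.sample or "unlabeled"] += 1
            lengths.append(r.read_length)
    clens = [len(seq) for _, seq in contigs.items()]
    return RunSummary(
        n_reads=n_reads,
        per_sample_reads=dict(sorted(per_sample.items())),
        mean_read_length=int(round_half_up(statistics.mean(lengths))) if lengths else None,
        n_contigs=len(clens),
        mean_contig_length=int(round_half_up(statistics.mean(clens))) if clens else None,
        median_contig_length=statistics.median(clens) if clens else None,
        total_contig_bases=sum(clens),
        n_snps=len(snps),
        n_snp_contigs=len({s.contig_id for s in snps}),
        n_haplotypes=sum(len(b.haplotypes) for b in blocks),
        n_blocks=len(blocks),
        n_block_contigs=len({b.contig_id for b in blocks}),
    )


def write_summary(summary: RunSummary, json_path: str | Path, text_path: str | Path | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(summary.pretty() + "\n")
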