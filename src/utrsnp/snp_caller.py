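"""Filter-cascade SNP calling on pileup columns, plus summary statistics.

A column becomes a SNP when, after removing observations from the first or
last ``end_exclusion`` bases of each read and all N/gap observations:

1. total effective depth >= ``min_total_depth`` (default 10);
2. the combined non-consensus fraction >= ``min_nonconsensus_frac``
   (default 0.20, boundary inclusive);
3. at least ``min_alleles`` (default 2) bases each reach
   ``min_allele_reads`` (default 3) supporting reads.

Gaps never count as alleles: indel polymorphism is notoriously unreliable in
pyrosequencing data and is excluded outright.  The consensus base is taken
from the input consensus FASTA (the assembler's call), falling back to the
majority base only when the FASTA base has no effective support.

Summary statistics cover the transition/transversion spectrum (the R value
= transitions / transversions over the six unordered base pairs) and SNP
density (bp per SNP, SNPs per kb).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .io_formats import ContigSet
from .pileup import Pileup, effective_counts

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

TRANSITION = "transition"
TRANSVERSION = "transversion"
MULTIALLELIC = "multiallelic"

#: the two unordered transition pairs; the other four ACGT pairs are
#: transversions
_TS_PAIRS = frozenset({frozenset("CT"), frozenset("AG")})

TS_PAIR_NAMES = ("C/T", "A/G")
TV_PAIR_NAMES = ("A/C", "A/T", "C/G", "G/T")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_substitution(a: str, b: str) -> str:
    """Classify an unordered base pair as transition or transversion."""
    if a not in _BASES or b not in _BASES:
        raise ValueError(f"bases must be A/C/G/T, got {a!r}/{b!r}")
    if a == b:
        raise ValueError(f"substitution requires two distinct bases, got {a!r} twice")
    return TRANSITION if frozenset((a, b)) in _TS_PAIRS else TRANSVERSION


def pair_name(a: str, b: str) -> str:
    """Canonical alphabetical label for an unordered base pair, e.g. 'A/G'."""
    x, y = sorted((a, b))
    return f"{x}/{y}"


@dataclass(frozen=True)
class SnpParams:
    min_total_depth: int = 10
    min_nonconsensus_frac: float = 0.20
    min_allele_reads: int = 3
    min_alleles: int = 2
    end_exclusion: int = 5

    def __post_init__(self):
        if min(self.min_total_depth, self.min_allele_reads, self.min_alleles, self.end_exclusion) < 0:
            raise ValueError("SnpParams thresholds must be >= 0")
        if not 0.0 <= self.min_nonconsensus_frac <= 1.0:
            raise ValueError("min_nonconsensus_frac must be in [0, 1]")


@dataclass
class SnpCall:
    contig_id: str
    pos: int  # 0-based internal
    consensus_base: str
    #: (base, read_count, per-sample Counter), sorted by descending count then base
    alleles: list[tuple[str, int, Counter]]
    total_effective_depth: int
    substitution_class: str
    flank5: str
    flank3: str
    #: full effective counts at the column (including sub-threshold bases)
    base_counts: dict[str, int] = field(default_factory=dict)
    sample_counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def allele_bases(self) -> tuple[str, ...]:
        return tuple(b for b, _, _ in self.alleles)


def call_snps(
    pileup: Pileup,
    consensus: ContigSet,
    params: SnpParams = SnpParams(),
    flank: int = 50,
) -> list[SnpCall]:
    """Apply the filter cascade to every pileup column.

    Returns calls sorted by (contig id, position).  Columns whose consensus
    base is N are skipped with a warning (no reference allele to measure
    variance against).
    """
    calls: list[SnpCall] = []
    for contig_id in sorted(pileup.columns):
        seq = consensus[contig_id]
        for pos in sorted(pileup.columns[contig_id]):
            col = pileup.columns[contig_id][pos]
            counts = effective_counts(col, params.end_exclusion)
            if not counts:
                continue
            total = sum(c for c, _ in counts.values())
            ref = seq[pos]
            if ref == "N":
                log.warning("skipping %s:%d: consensus base is N", contig_id, pos + 1)
                continue
            if ref in counts and counts[ref][0] > 0:
                cons = ref
            else:
                # assembler base unsupported here: fall back to majority vote
                cons = max(counts, key=lambda b: (counts[b][0], -ord(b)))
            if total < params.min_total_depth:
                continue
            noncons = total - counts.get(cons, (0, None))[0]
            if noncons / total < params.min_nonconsensus_frac:
                continue
            alleles = [
                (b, counts[b][0], counts[b][1])
                for b in _BASES
                if b in counts and counts[b][0] >= params.min_allele_reads
            ]
            if len(alleles) < params.min_alleles:
                continue
            alleles.sort(key=lambda t: (-t[1], t[0]))
            if len(alleles) == 2:
                sub_class = classify_substitution(alleles[0][0], alleles[1][0])
            else:
                sub_class = MULTIALLELIC
            calls.append(
                SnpCall(
                    contig_id=contig_id,
                    pos=pos,
                    consensus_base=cons,
                    alleles=alleles,
                    total_effective_depth=total,
                    substitution_class=sub_class,
                    flank5=seq[max(0, pos - flank) : pos],
                    flank3=seq[pos + 1 : pos + 1 + flank],
                    base_counts={b: counts[b][0] for b in _BASES if b in counts},
                    sample_counts={b: counts[b][1] for b in _BASES if b in counts},
                )
            )
    return calls


@dataclass
class SnpStats:
    n_snps: int
    transitions_by_pair: dict[str, int]
    transversions_by_pair: dict[str, int]
    ts_total: int
    tv_total: int
    r_value: float | None
    total_bases: int
    snps_per_kb: float | None
    bp_per_snp: int | None

    def as_dict(self) -> dict:
        return {
            "n_snps": self.n_snps,
            "transitions_by_pair": self.transitions_by_pair,
            "transversions_by_pair": self.transversions_by_pair,
            "ts_total": self.ts_total,
            "tv_total": self.tv_total,
            "r_value": self.r_value,
            "total_bases": self.total_bases,
            "snps_per_kb": self.snps_per_kb,
            "bp_per_snp": self.bp_per_snp,
        }


def stats_from_pair_counts(
    pair_counts: Mapping[str, int], n_snps: int, total_bases: int
) -> SnpStats:
    """Assemble summary statistics from unordered-pair substitution counts.

    ``pair_counts`` keys are pair labels in either base order ('C/T' and
    'T/C' are the same pair).  The R value is rounded to 2 decimals; density
    statistics follow printed precision (bp/SNP to the nearest integer,
    SNPs/kb to 2 decimals).
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    canon: Counter = Counter()
    for name, count in pair_counts.items():
        a, _, b = name.partition("/")
        canon[pair_name(a, b)] += count
    ts = {p: canon.get(p, 0) for p in TS_PAIR_NAMES}
    tv = {p: canon.get(p, 0) for p in TV_PAIR_NAMES}
    ts_total, tv_total = sum(ts.values()), sum(tv.values())
    r_value = round_half_up(ts_total / tv_total, 2) if tv_total > 0 else None
    if n_snps > 0:
        snps_per_kb = round_half_up(n_snps / (total_bases / 1000), 2)
        bp_per_snp = int(round_half_up(total_bases / n_snps))
    else:
        snps_per_kb = bp_per_snp = None
    return SnpStats(
        n_snps=n_snps,
        transitions_by_pair=ts,
        transversions_by_pair=tv,
        ts_total=ts_total,
        tv_total=tv_total,
        r_value=r_value,
        total_bases=total_bases,
        snps_per_kb=snps_per_kb,
        bp_per_snp=bp_per_snp,
    )


def compute_stats(snps: Sequence[SnpCall], total_bases: int) -> SnpStats:
    """Summarize a call set.

    Biallelic calls are classified into the six unordered base pairs; sites
    with more than two alleles count toward ``n_snps`` but are excluded from
    the transition/transversion spectrum, which is defined on base pairs.
    """
    pairs: Counter = Counter()
    for snp in snps:
        if len(snp.alleles) == 2:
            pairs[pair_name(snp.alleles[0][0], snp.alleles[1][0])] += 1
    return stats_from_pair_counts(pairs, len(snps), total_bases)
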