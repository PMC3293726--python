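"""Per-contig, per-position base observation columns.

The pileup is the shared substrate for SNP calling and haplotype linking:
every observation keeps its read identity, sample label and distance from
the nearer read end, so that downstream filters can (a) exclude calls
supported only by read ends and (b) trace which reads span pairs of
polymorphic sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import GAP, AlignedRead, ContigSet

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Observation:
    """A single read's contribution to one contig position.

    ``end_distance`` = min(read_offset, read_length-1-read_offset), i.e. how
    far this base sits from the nearer end of the read (0 = terminal base).
    It is None for deletion gaps, which have no read base.
    """

    read_id: str
    sample: str
    base: str  # A/C/G/T/N or GAP
    read_offset: int | None
    end_distance: int | None


@dataclass
class PileupColumn:
    contig_id: str
    pos: int  # 0-based contig offset
    observations: list[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class Pileup:
    """columns: contig -> {pos -> PileupColumn}; insertions are kept on a
    side channel keyed by (contig, preceding contig position) and never form
    columns (only consensus positions are callable; indels are excluded from
    calling anyway)."""

    columns: dict[str, dict[int, PileupColumn]] = field(default_factory=dict)
    insertions: dict[tuple[str, int], list[Observation]] = field(default_factory=dict)

    def contig_columns(self, contig_id: str) -> list[PileupColumn]:
        cols = self.columns.get(contig_id, {})
        return [cols[p] for p in sorted(cols)]

    def column(self, contig_id: str, pos: int) -> PileupColumn | None:
        return self.columns.get(contig_id, {}).get(pos)


def build_pileup(reads: Iterable[AlignedRead], contigs: ContigSet) -> Pileup:
    """Accumulate observations column by column.

    Match/mismatch pairs become base observations; deletion pairs become GAP
    observations; insertion pairs are recorded on the insertion side channel.
    A read contributes at most one observation per column.
    """
    pile = Pileup()
    for read in reads:
        if read.contig_id not in contigs:
            raise ValueError(f"read {read.read_id!r} references unknown contig {read.contig_id!r}")
        clen = len(contigs[read.contig_id])
        cols = pile.columns.setdefault(read.contig_id, {})
        last_ref = read.ref_start - 1
        for qoff, roff, base in read.aligned_pairs:
            if roff is None:
                obs = Observation(read.read_id, read.sample, base, qoff, None)
                pile.insertions.setdefault((read.contig_id, last_ref), []).append(obs)
                continue
            if roff >= clen:
                raise ValueError(f"read {read.read_id!r} aligns past end of contig {read.contig_id!r}")
            last_ref = roff
            if qoff is None:
                obs = Observation(read.read_id, read.sample, GAP, None, None)
            else:
                end_dist = min(qoff, read.read_length - 1 - qoff)
                obs = Observation(read.read_id, read.sample, base, qoff, end_dist)
            col = cols.get(roff)
            if col is None:
                col = cols[roff] = PileupColumn(read.contig_id, roff)
            col.observations.append(obs)
    return pile


def effective_counts(
    col: PileupColumn, end_exclusion: int
) -> dict[str, tuple[int, Counter]]:
    """Per-base (read_count, per_sample_counts) after end exclusion.

    Observations whose base lies within ``end_exclusion`` bases of either
    read end are discarded, as are N and gap observations: the result covers
    A/C/G/T only.  With ``end_exclusion=5`` this implements rejection of
    calls arising from the first or last five bases of a read
    (end_distance 0..4 excluded).
    """
    if end_exclusion < 0:
        raise ValueError("end_exclusion must be >= 0")
    out: dict[str, tuple[int, Counter]] = {}
    for obs in col.observations:
        if obs.base not in _BASES:
            continue
        if obs.end_distance is not None and obs.end_distance < end_exclusion:
            continue
        count, per_sample = out.get(obs.base, (0, Counter()))
        per_sample[obs.sample] += 1
        out[obs.base] = (count + 1, per_sample)
    return out


def effective_depth(counts: Mapping[str, tuple[int, Counter]]) -> int:
    return sum(c for c, _ in counts.values())
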