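"""Read-backed haplotype linking of called SNP loci.

Two SNP loci on a contig are linked when at least ``min_span_reads``
(default 3) reads carry the same allele pair across both loci.  Linked loci
form blocks (connected components of the link graph, so linking is
transitive); within each block, reads covering two or more loci are grouped
into segments, segments are merged along unique compatible overlaps, and the
resulting allele strings — padded with '?' where no segment reaches — are
the block's haplotypes.  A '?' marks incomplete depth for a confirmed call
at that locus.

End exclusion is applied to haplotype support exactly as to SNP support, and
only bases that are alleles of the respective SNP call contribute; everything
else (sequencing error, sub-threshold bases, read-end bases) is noise and is
silently dropped rather than reported as a rare haplotype.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .pileup import Pileup
from .snp_caller import SnpCall

UNKNOWN = "?"


@dataclass(frozen=True)
class HaploParams:
    min_span_reads: int = 3
    end_exclusion: int = 5  # shared with the SNP filter cascade

    def __post_init__(self):
        if self.min_span_reads < 1:
            raise ValueError("min_span_reads must be >= 1")
        if self.end_exclusion < 0:
            raise ValueError("end_exclusion must be >= 0")


@dataclass
class LinkEdge:
    contig_id: str
    pos_a: int
    pos_b: int  # pos_a < pos_b
    #: (base_a, base_b) -> (read_count, per-sample Counter); only observed pairs
    supported_pairs: dict[tuple[str, str], tuple[int, Counter]]

    def max_support(self) -> int:
        return max((c for c, _ in self.supported_pairs.values()), default=0)


@dataclass
class Haplotype:
    allele_string: str
    read_support: int
    per_sample_support: Counter


@dataclass
class HaplotypeBlock:
    contig_id: str
    region_label: str  # A, B, C, ... left-to-right within the contig
    positions: tuple[int, ...]  # sorted 0-based SNP positions
    haplotypes: list[Haplotype]


def region_label(index: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet-style labels)."""
    label = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def _allele_observations(
    pileup: Pileup, snps: Sequence[SnpCall], params: HaploParams
) -> dict[str, dict[int, dict[str, tuple[str, str]]]]:
    """contig -> pos -> read_id -> (base, sample), keeping only effective
    observations whose base is an allele of the SNP at that position."""
    out: dict[str, dict[int, dict[str, tuple[str, str]]]] = defaultdict(dict)
    for snp in snps:
        col = pileup.column(snp.contig_id, snp.pos)
        if col is None:
            continue
        allowed = set(snp.allele_bases)
        by_read: dict[str, tuple[str, str]] = {}
        for obs in col.observations:
            if obs.end_distance is None or obs.end_distance < params.end_exclusion:
                continue
            if obs.base in allowed:
                by_read[obs.read_id] = (obs.base, obs.sample)
        out[snp.contig_id][snp.pos] = by_read
    return out


def build_link_graph(
    pileup: Pileup, snps: Sequence[SnpCall], params: HaploParams = HaploParams()
) -> list[LinkEdge]:
    """Edges between SNP loci supported by >= min_span_reads spanning reads.

    For every pair of called loci on a contig, reads with effective allele
    observations at both loci are tallied by their (base_a, base_b) pair; an
    edge is emitted iff some pair reaches the threshold.  All observed pairs
    are retained on the edge (chimeric sub-threshold pairs included, for
    inspection), but only the threshold decides linkage.
    """
    obs_map = _allele_observations(pileup, snps, params)
    edges: list[LinkEdge] = []
    for contig_id in sorted(obs_map):
        positions = sorted(obs_map[contig_id])
        for i, pa in enumerate(positions):
            reads_a = obs_map[contig_id][pa]
            for pb in positions[i + 1 :]:
                reads_b = obs_map[contig_id][pb]
                pair_counts: dict[tuple[str, str], tuple[int, Counter]] = {}
                for rid in reads_a.keys() & reads_b.keys():
                    ba, sample = reads_a[rid]
                    bb, _ = reads_b[rid]
                    count, per_sample = pair_counts.get((ba, bb), (0, Counter()))
                    per_sample[sample] += 1
                    pair_counts[(ba, bb)] = (count + 1, per_sample)
                if any(c >= params.min_span_reads for c, _ in pair_counts.values()):
                    edges.append(LinkEdge(contig_id, pa, pb, pair_counts))
    return edges


def find_blocks(edges: Iterable[LinkEdge]) -> list[tuple[int, ...]]:
    """Connected components of the locus link graph for ONE contig,
    returned left-to-right as sorted position tuples.  Singleton loci form
    no block (a haplotype needs at least two SNPs)."""
    g = nx.Graph()
    contigs = {e.contig_id for e in edges}
    if len(contigs) > 1:
        raise ValueError(f"find_blocks expects edges from one contig, got {sorted(contigs)}")
    for e in edges:
        g.add_edge(e.pos_a, e.pos_b)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: c[0])
    return comps


@dataclass
class _Segment:
    alleles: dict[int, str]  # pos -> base
    support: int

    def key(self) -> tuple:
        return tuple(sorted(self.alleles.items()))


def _compatible_extension(a: _Segment, b: _Segment) -> bool:
    shared = a.alleles.keys() & b.alleles.keys()
    if not shared:
        return False
    if any(a.alleles[p] != b.alleles[p] for p in shared):
        return False
    return bool(b.alleles.keys() - a.alleles.keys()) or bool(a.alleles.keys() - b.alleles.keys())


def _merge_segments(segments: list[_Segment]) -> list[_Segment]:
    """Greedy fixpoint merge along mutually unique compatible overlaps.

    If two different segments could extend the same overlap, neither merge is
    performed: inventing recombinants not witnessed by any read is worse than
    leaving a '?'.
    """
    segs = list(segments)
    merged = True
    while merged:
        merged = False
        partners: list[list[int]] = []
        for i, s in enumerate(segs):
            partners.append([j for j, t in enumerate(segs) if j != i and _compatible_extension(s, t)])
        for i, plist in enumerate(partners):
            if len(plist) != 1:
                continue
            j = plist[0]
            if partners[j] != [i]:  # mutual uniqueness required
                continue
            a, b = segs[i], segs[j]
            union = dict(a.alleles)
            union.update(b.alleles)
            segs = [s for k, s in enumerate(segs) if k not in (i, j)]
            segs.append(_Segment(union, a.support + b.support))
            merged = True
            break
        # collapse exact duplicates that merging may have produced
        by_key: dict[tuple, _Segment] = {}
        for s in segs:
            k = s.key()
            if k in by_key:
                by_key[k].support += s.support
            else:
                by_key[k] = _Segment(dict(s.alleles), s.support)
        segs = list(by_key.values())
    return segs


def _fold_subsumed(strings: list[dict[int, str]]) -> list[dict[int, str]]:
    """Fold a string into a unique superstring that agrees at all of its
    defined loci ('?'-masked identity): the difference between the two is no
    longer traceable, so they are one haplotype."""
    folded = True
    while folded:
        folded = False
        for i, s in enumerate(strings):
            supers = [
                j
                for j, t in enumerate(strings)
                if j != i
                and s.keys() <= t.keys()
                and all(t[p] == b for p, b in s.items())
            ]
            if len(supers) == 1:
                strings = [t for k, t in enumerate(strings) if k != i]
                folded = True
                break
    return strings


def enumerate_haplotypes(
    positions: Sequence[int],
    contig_id: str,
    pileup: Pileup,
    snps: Sequence[SnpCall],
    params: HaploParams = HaploParams(),
    label: str = "A",
) -> HaplotypeBlock | None:
    """Enumerate supported allele strings over one block of linked loci.

    Pipeline: read fragments (>=2 covered loci) -> identical fragments
    grouped into segments (>= min_span_reads) -> unique-overlap merge ->
    '?' fill -> fold '?'-masked duplicates.  A haplotype's reported support
    is the number of fragments consistent with it and with no other reported
    haplotype; blocks with fewer than two haplotypes are dropped.
    """
    positions = tuple(sorted(positions))
    if len(positions) < 2:
        return None
    block_snps = [s for s in snps if s.contig_id == contig_id and s.pos in set(positions)]
    obs_map = _allele_observations(pileup, block_snps, params).get(contig_id, {})

    fragments: dict[str, dict[int, str]] = defaultdict(dict)
    frag_sample: dict[str, str] = {}
    for pos in positions:
        for rid, (base, sample) in obs_map.get(pos, {}).items():
            fragments[rid][pos] = base
            frag_sample[rid] = sample
    fragments = {rid: f for rid, f in fragments.items() if len(f) >= 2}

    groups: dict[tuple, _Segment] = {}
    for frag in fragments.values():
        k = tuple(sorted(frag.items()))
        if k in groups:
            groups[k].support += 1
        else:
            groups[k] = _Segment(dict(frag), 1)
    segments = [s for s in groups.values() if s.support >= params.min_span_reads]
    if not segments:
        return None

    merged = _merge_segments(segments)
    strings = _fold_subsumed([s.alleles for s in merged])
    if len(strings) < 2:
        return None

    haplotypes: list[Haplotype] = []
    for s in strings:
        allele_string = "".join(s.get(p, UNKNOWN) for p in positions)
        haplotypes.append(Haplotype(allele_string, 0, Counter()))

    def consistent(frag: dict[int, str], s: dict[int, str]) -> bool:
        return all(p not in s or s[p] == b for p, b in frag.items())

    for rid, frag in fragments.items():
        hits = [h for h, s in zip(haplotypes, strings) if consistent(frag, s)]
        if len(hits) == 1:
            hits[0].read_support += 1
            hits[0].per_sample_support[frag_sample[rid]] += 1

    haplotypes.sort(key=lambda h: (-h.read_support, h.allele_string))
    return HaplotypeBlock(contig_id, label, positions, haplotypes)


def phase(
    pileup: Pileup, snps: Sequence[SnpCall], params: HaploParams = HaploParams()
) -> list[HaplotypeBlock]:
    """Full haplotyping pass: link graph -> blocks -> enumerated haplotypes,
    with region labels restarting at 'A' on each contig."""
    edges = build_link_graph(pileup, snps, params)
    by_contig: dict[str, list[LinkEdge]] = defaultdict(list)
    for e in edges:
        by_contig[e.contig_id].append(e)
    blocks: list[HaplotypeBlock] = []
    for contig_id in sorted(by_contig):
        kept = []
        for comp in find_blocks(by_contig[contig_id]):
            blk = enumerate_haplotypes(comp, contig_id, pileup, snps, params, label="?")
            if blk is not None:
                kept.append(blk)
        for i, blk in enumerate(kept):
            blk.region_label = region_label(i)
            blocks.append(blk)
    return blocks
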