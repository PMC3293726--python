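"""Shared helpers and independent oracle implementations for the tests.

The oracles here deliberately re-derive results from first principles
(literal enumeration over reads, union-find, manual CIGAR walking) without
touching the package's pileup/caller/graph code paths.
"""

from __future__ import annotations

import random
from collections import Counter

from utrsnp.io_formats import AlignedRead, ContigSet
from utrsnp.snp_caller import SnpCall, SnpParams


def make_read(read_id: str, contig: str, start: int, seq: str, sample: str = "") -> AlignedRead:
    """A gapless read aligned at `start` (0-based)."""
    pairs = tuple((i, start + i, seq[i]) for i in range(len(seq)))
    return AlignedRead(read_id, sample, contig, start, pairs, len(seq))


def make_snp(contig: str, pos: int, alleles: list[tuple[str, int]], consensus: str | None = None) -> SnpCall:
    """Minimal SnpCall for haplotyper/report tests."""
    full = [(b, c, Counter({"": c})) for b, c in alleles]
    return SnpCall(
        contig_id=contig,
        pos=pos,
        consensus_base=consensus or alleles[0][0],
        alleles=full,
        total_effective_depth=sum(c for _, c in alleles),
        substitution_class="transition" if len(alleles) == 2 else "multiallelic",
        flank5="",
        flank3="",
        base_counts={b: c for b, c in alleles},
        sample_counts={b: Counter({"": c}) for b, c in alleles},
    )


def expand_cigar_by_hand(pos: int, cigar: list[tuple[str, int]], seq: str):
    """Independent CIGAR walker: returns (pairs, read_length) in the same
    triple convention as AlignedRead.aligned_pairs."""
    pairs = []
    q, r = 0, pos
    for op, n in cigar:
        if op in "M=X":
            for _ in range(n):
                pairs.append((q, r, seq[q]))
                q += 1
                r += 1
        elif op == "I":
            for _ in range(n):
                pairs.append((q, None, seq[q]))
                q += 1
        elif op in "DN":
            for _ in range(n):
                pairs.append((None, r, "-"))
                r += 1
        elif op == "S":
            q += n
        elif op in "HP":
            pass
        else:
            raise ValueError(op)
    return pairs, q


def oracle_call_snps(reads: list[AlignedRead], consensus: ContigSet, params: SnpParams):
    """Literal re-derivation of the filter cascade straight from the reads.

    Returns a set of (contig, pos, consensus_base, ((base, count), ...), depth)
    tuples with alleles sorted by descending count then base.
    """
    sites: dict[tuple[str, int], list[str]] = {}
    for read in reads:
        for qoff, roff, base in read.aligned_pairs:
            if roff is None or qoff is None:
                continue
            if base not in "ACGT":
                continue
            if min(qoff, read.read_length - 1 - qoff) < params.end_exclusion:
                continue
            sites.setdefault((read.contig_id, roff), []).append(base)
    out = set()
    for (cid, pos), bases in sites.items():
        counts = Counter(bases)
        total = sum(counts.values())
        ref = consensus[cid][pos]
        if ref == "N":
            continue
        if counts.get(ref, 0) > 0:
            cons = ref
        else:
            best = max(counts.values())
            cons = min(b for b in counts if counts[b] == best)
        if total < params.min_total_depth:
            continue
        if (total - counts.get(cons, 0)) / total < params.min_nonconsensus_frac:
            continue
        alleles = [(b, c) for b, c in counts.items() if c >= params.min_allele_reads]
        if len(alleles) < params.min_alleles:
            continue
        alleles.sort(key=lambda t: (-t[1], t[0]))
        out.add((cid, pos, cons, tuple(alleles), total))
    return out


def snapshot_calls(calls: list[SnpCall]):
    return {
        (
            s.contig_id,
            s.pos,
            s.consensus_base,
            tuple((b, c) for b, c, _ in s.alleles),
            s.total_effective_depth,
        )
        for s in calls
    }


def union_find_components(edges: list[tuple[int, int]]) -> list[tuple[int, ...]]:
    """Brute-force connected components over integer nodes."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    comps = [tuple(sorted(g)) for g in groups.values() if len(g) >= 2]
    comps.sort(key=lambda c: c[0])
    return comps


def random_instance(rng: random.Random):
    """A small random contig + noisy read set for oracle-equivalence tests."""
    clen = rng.randrange(30, 60)
    seq = "".join(rng.choice("ACGT") for _ in range(clen))
    contigs = ContigSet({"c": seq})
    reads = []
    for i in range(rng.randrange(10, 40)):
        length = rng.randrange(8, 20)
        start = rng.randrange(0, clen - length + 1)
        bases = []
        for j in range(length):
            r = rng.random()
            if r < 0.70:
                bases.append(seq[start + j])
            elif r < 0.95:
                bases.append(rng.choice("ACGT"))
            else:
                bases.append("N")
        reads.append(make_read(f"r{i}", "c", start, "".join(bases)))
    return contigs, reads


def random_params(rng: random.Random) -> SnpParams:
    return SnpParams(
        min_total_depth=rng.randrange(2, 7),
        min_nonconsensus_frac=rng.choice([0.0, 0.1, 0.2, 0.3]),
        min_allele_reads=rng.randrange(1, 4),
        min_alleles=2,
        end_exclusion=rng.randrange(0, 4),
    )
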