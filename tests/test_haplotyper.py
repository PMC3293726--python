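"""Read-backed linking of SNP loci into haplotype blocks."""

import random

import pytest

from testutil import make_read, make_snp, union_find_components
from utrsnp.haplotyper import (
    HaploParams,
    LinkEdge,
    build_link_graph,
    enumerate_haplotypes,
    find_blocks,
    phase,
    region_label,
)
from utrsnp.io_formats import ContigSet
from utrsnp.pileup import build_pileup

P0 = HaploParams(min_span_reads=3, end_exclusion=0)


def contig(length=400):
    return ContigSet({"c": "A" * length})


def spanning_reads(allele_pairs, pos_a=50, pos_b=60, contig_id="c", prefix="s"):
    """Reads covering [pos_a, pos_b] carrying the given allele pairs."""
    reads = []
    i = 0
    for (base_a, base_b), count in allele_pairs.items():
        for _ in range(count):
            seq = list("A" * (pos_b - pos_a + 1))
            seq[0] = base_a
            seq[-1] = base_b
            reads.append(make_read(f"{prefix}{i}", contig_id, pos_a, "".join(seq)))
            i += 1
    return reads


class TestLinkGraph:
    def test_pairs_counted_per_read(self):
        reads = spanning_reads({("A", "C"): 5, ("G", "T"): 4})
        snps = [make_snp("c", 50, [("A", 5), ("G", 4)]), make_snp("c", 60, [("C", 5), ("T", 4)])]
        pile = build_pileup(reads, contig())
        (edge,) = build_link_graph(pile, snps, P0)
        assert (edge.pos_a, edge.pos_b) == (50, 60)
        assert {k: v[0] for k, v in edge.supported_pairs.items()} == {("A", "C"): 5, ("G", "T"): 4}

    def test_below_threshold_pairs_do_not_link(self):
        reads = spanning_reads({("A", "T"): 2})
        snps = [make_snp("c", 50, [("A", 3), ("G", 3)]), make_snp("c", 60, [("T", 3), ("C", 3)])]
        pile = build_pileup(reads, contig())
        assert build_link_graph(pile, snps, P0) == []

    def test_no_spanning_reads_no_edge(self):
        # loci 200 bp apart, reads only 100 bp
        reads = [make_read(f"a{i}", "c", 0, "G" + "A" * 99) for i in range(5)]
        reads += [make_read(f"b{i}", "c", 150, "A" * 50 + "T" + "A" * 49) for i in range(5)]
        snps = [make_snp("c", 0, [("G", 5), ("A", 3)]), make_snp("c", 200, [("T", 5), ("A", 3)])]
        pile = build_pileup(reads, contig())
        assert build_link_graph(pile, snps, P0) == []

    def test_non_allele_bases_do_not_contribute(self):
        reads = spanning_reads({("A", "C"): 2, ("T", "C"): 3})  # T not an allele at locus 50
        snps = [make_snp("c", 50, [("A", 5), ("G", 4)]), make_snp("c", 60, [("C", 5), ("T", 4)])]
        pile = build_pileup(reads, contig())
        assert build_link_graph(pile, snps, P0) == []


def edge(a, b, contig_id="c"):
    return LinkEdge(contig_id, a, b, {})


class TestFindBlocks:
    def test_transitive_linking(self):
        assert find_blocks([edge(1, 2), edge(2, 3)]) == [(1, 2, 3)]

    def test_disjoint_components(self):
        assert find_blocks([edge(1, 2), edge(4, 5)]) == [(1, 2), (4, 5)]

    def test_no_edges_no_blocks(self):
        assert find_blocks([]) == []

    def test_mixed_contigs_rejected(self):
        with pytest.raises(ValueError):
            find_blocks([edge(1, 2, "c1"), edge(3, 4, "c2")])

    def test_matches_union_find_on_random_graphs(self):
        rng = random.Random(31)
        for _ in range(100):
            nodes = rng.randrange(2, 15)
            pairs = set()
            for _ in range(rng.randrange(1, 12)):
                a, b = rng.sample(range(nodes), 2)
                pairs.add((min(a, b), max(a, b)))
            edges = [edge(a, b) for a, b in pairs]
            assert find_blocks(edges) == union_find_components(sorted(pairs))

    def test_region_labels_are_spreadsheet_style(self):
        assert [region_label(i) for i in (0, 1, 25, 26, 27)] == ["A", "B", "Z", "AA", "AB"]


def block_reads(fragments, positions, contig_id="c"):
    """Reads realizing partial allele strings; '.' = locus not covered.
    Each fragment covers a contiguous run of block loci."""
    reads = []
    i = 0
    for alleles, count in fragments:
        covered = [k for k, a in enumerate(alleles) if a != "."]
        lo, hi = positions[covered[0]], positions[covered[-1]]
        for _ in range(count):
            seq = list("A" * (hi - lo + 1))
            for k in covered:
                seq[positions[k] - lo] = alleles[k]
            reads.append(make_read(f"f{i}", contig_id, lo, "".join(seq)))
            i += 1
    return reads


class TestEnumerateHaplotypes:
    def snps_at(self, positions, allele_sets):
        return [make_snp("c", p, [(b, 5) for b in bases]) for p, bases in zip(positions, allele_sets)]

    def test_two_locus_two_haplotypes(self):
        positions = (50, 60)
        reads = block_reads([("AC", 11), ("GT", 9)], positions)
        snps = self.snps_at(positions, ["AG", "CT"])
        pile = build_pileup(reads, contig())
        blk = enumerate_haplotypes(positions, "c", pile, snps, P0)
        assert [(h.allele_string, h.read_support) for h in blk.haplotypes] == [("AC", 11), ("GT", 9)]

    def test_unique_overlap_merge_extends_segments(self):
        positions = (50, 60, 70)
        reads = block_reads([("AC.", 5), (".CG", 4), ("GT.", 5), (".TA", 4)], positions)
        snps = self.snps_at(positions, ["AG", "CT", "GA"])
        pile = build_pileup(reads, contig())
        blk = enumerate_haplotypes(positions, "c", pile, snps, P0)
        assert {h.allele_string for h in blk.haplotypes} == {"ACG", "GTA"}

    def test_unbridgeable_segments_get_question_marks(self):
        positions = (50, 60, 70)
        reads = block_reads([("AC.", 5), (".TG", 5)], positions)
        snps = self.snps_at(positions, ["AG", "CT", "GA"])
        pile = build_pileup(reads, contig())
        blk = enumerate_haplotypes(positions, "c", pile, snps, P0)
        assert {h.allele_string for h in blk.haplotypes} == {"AC?", "?TG"}
        assert [h.read_support for h in blk.haplotypes] == [5, 5]

    def test_ambiguous_merge_is_not_performed(self):
        # the (.CG) bridge could extend either AC. or GC. -> no merge invented
        positions = (50, 60, 70)
        reads = block_reads([("AC.", 5), ("GC.", 5), (".CG", 4), (".CT", 4)], positions)
        snps = self.snps_at(positions, ["AG", "C", "GT"])
        pile = build_pileup(reads, contig())
        blk = enumerate_haplotypes(positions, "c", pile, snps, P0)
        for h in blk.haplotypes:
            assert "?" in h.allele_string  # nothing spans all three loci

    def test_sub_threshold_chimeras_dropped(self):
        positions = (50, 60)
        reads = block_reads([("AC", 8), ("GT", 7), ("AT", 2)], positions)
        snps = self.snps_at(positions, ["AG", "CT"])
        pile = build_pileup(reads, contig())
        blk = enumerate_haplotypes(positions, "c", pile, snps, P0)
        assert {h.allele_string for h in blk.haplotypes} == {"AC", "GT"}

    def test_single_haplotype_block_dropped(self):
        positions = (50, 60)
        reads = block_reads([("AC", 10)], positions)
        snps = self.snps_at(positions, ["AG", "CT"])
        pile = build_pileup(reads, contig())
        assert enumerate_haplotypes(positions, "c", pile, snps, P0) is None

    def test_support_bounded_by_spanning_reads(self):
        rng = random.Random(8)
        positions = (50, 60, 70)
        frags = [
            ("".join(rng.choice("ACGT") for _ in positions), rng.randrange(1, 6))
            for _ in range(6)
        ]
        reads = block_reads(frags, positions)
        snps = self.snps_at(positions, ["ACGT", "ACGT", "ACGT"])
        pile = build_pileup(reads, contig())
        blk = enumerate_haplotypes(positions, "c", pile, snps, P0)
        if blk is not None:
            total_support = sum(h.read_support for h in blk.haplotypes)
            assert total_support <= sum(c for _, c in frags)


class TestPhase:
    def test_labels_restart_per_contig_left_to_right(self):
        contigs = ContigSet({"c": "A" * 400, "d": "A" * 400})
        reads = spanning_reads({("A", "C"): 5, ("G", "T"): 4}, 50, 60, "c", prefix="p")
        reads += spanning_reads({("C", "A"): 5, ("T", "G"): 4}, 250, 260, "c", prefix="q")
        reads += spanning_reads({("A", "C"): 5, ("G", "T"): 4}, 30, 40, "d", prefix="w")
        snps = [
            make_snp("c", 50, [("A", 5), ("G", 4)]),
            make_snp("c", 60, [("C", 5), ("T", 4)]),
            make_snp("c", 250, [("C", 5), ("T", 4)]),
            make_snp("c", 260, [("A", 5), ("G", 4)]),
            make_snp("d", 30, [("A", 5), ("G", 4)]),
            make_snp("d", 40, [("C", 5), ("T", 4)]),
        ]
        pile = build_pileup(reads, contigs)
        blocks = phase(pile, snps, P0)
        labels = [(b.contig_id, b.region_label, b.positions) for b in blocks]
        assert labels == [
            ("c", "A", (50, 60)),
            ("c", "B", (250, 260)),
            ("d", "A", (30, 40)),
        ]

    def test_planted_haplotypes_recovered_without_gaps(self, sim_bundle, sim_pipeline):
        """Two planted haplotypes per multi-SNP block come back verbatim."""
        cfg, truth, readset, _ = sim_bundle
        contigs, reads, pile, snps = sim_pipeline
        blocks = phase(pile, snps)
        reported = {(b.contig_id, b.positions): {h.allele_string for h in b.haplotypes} for b in blocks}
        n_checked = 0
        for cid, contig_blocks in truth.blocks.items():
            for positions in contig_blocks:
                if len(positions) < 2:
                    continue
                n_checked += 1
                expected = set(truth.block_allele_strings(cid, positions))
                assert reported.get((cid, tuple(positions))) == expected
        assert n_checked >= 1

    def test_consecutive_pairs_backed_by_min_span_reads(self, sim_bundle, sim_pipeline):
        cfg, truth, readset, _ = sim_bundle
        contigs, reads, pile, snps = sim_pipeline
        params = HaploParams()
        blocks = phase(pile, snps, params)
        # brute recount of spanning reads straight from the read set
        for blk in blocks:
            for hap in blk.haplotypes:
                defined = [
                    (p, a) for p, a in zip(blk.positions, hap.allele_string) if a != "?"
                ]
                for (pa, ba), (pb, bb) in zip(defined, defined[1:]):
                    n = 0
                    for r in reads:
                        if r.contig_id != blk.contig_id:
                            continue
                        bases = {
                            roff: (base, qoff)
                            for qoff, roff, base in r.aligned_pairs
                            if roff in (pa, pb) and qoff is not None
                        }
                        if len(bases) < 2:
                            continue
                        ok = True
                        for pos, want in ((pa, ba), (pb, bb)):
                            base, qoff = bases[pos]
                            if base != want or min(qoff, r.read_length - 1 - qoff) < params.end_exclusion:
                                ok = False
                        n += ok
                    assert n >= params.min_span_reads
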