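import numpy as np
import pytest

from dechip import assemble_dbg as dbg
from dechip._seqtools import count_canonical_kmers, revcomp
from tests.conftest import random_seq, random_source, tiling_reads


def graph_from_seqs(seqs, k):
    u, c = count_canonical_kmers(seqs, k)
    g = dbg._graph_from_kmers(dict(zip(u.tolist(), c.tolist())), k)
    g.validate()
    return g


class TestParams:
    def test_k_lower_bound(self):
        with pytest.raises(ValueError):
            dbg.AssemblyParams(k=9)

    def test_tip_cutoff_default(self):
        assert dbg.AssemblyParams(k=17).tip_cutoff == 34


class TestBuildGraph:
    def test_single_linear_read(self):
        # a read without reverse-complement self-overlap merges to one pair
        read = "AAGGCTGTTAC"
        g = graph_from_seqs([read], 4)
        assert len(g.nodes) == 1
        (node,) = g.nodes.values()
        assert node.seq in (read, revcomp(read))

    def test_self_rc_read_is_handled_without_duplication(self):
        # 'ACGTACG' walks onto its own reverse complement (k=4); a paired
        # graph represents this as a hairpin, not a single 7-bp node, but
        # every k-mer must appear exactly once and the graph must validate
        g = graph_from_seqs(["ACGTACG"], 4)
        total_kmers = sum(n.nk for n in g.nodes.values())
        assert total_kmers == 3  # ACGT, CGTA/TACG pair, GTAC

    def test_palindromic_kmer_self_twin(self):
        g = graph_from_seqs(["ACGT"], 4)
        assert len(g.nodes) == 1
        (node,) = g.nodes.values()
        assert node.seq == "ACGT" == revcomp(node.seq)

    def test_tiling_reads_single_node_pair(self, rng):
        src = random_source(rng, 300)
        reads = tiling_reads(src, 250, 36)
        g = dbg.build_graph(reads, dbg.AssemblyParams(k=17))
        g.validate()
        assert len(g.nodes) == 1
        (node,) = g.nodes.values()
        assert node.seq in (src, revcomp(src))

    def test_short_reads_skipped_and_empty_errors(self):
        with pytest.raises(ValueError, match="no reads"):
            dbg.build_graph(["ACGT"], dbg.AssemblyParams(k=17))

    def test_coverage_counts(self):
        g = graph_from_seqs(["AAGGCTGTTAC"] * 7, 4)
        (node,) = g.nodes.values()
        assert node.cov == 7 * 8  # 8 k-mers per read, 7 reads
        assert node.mean_cov == pytest.approx(7.0)


class TestRemoveTips:
    def _branchy(self, rng, k=17):
        """Main 300-bp path plus a dead-end branch diverging mid-way."""
        src = random_source(rng, 300)
        return src

    def test_short_low_coverage_tip_removed(self, rng):
        src = self._branchy(rng)
        # tip: divergent continuation of length k after position 150
        tip = src[150 - 16 : 150] + random_seq(rng, 17)
        reads = tiling_reads(src, 120, 36) * 2 + [tip]
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(reads, params)
        assert len(g.nodes) > 1
        dbg.remove_tips(g, params)
        g.validate()
        assert len(g.nodes) == 1
        (node,) = g.nodes.values()
        assert node.seq in (src, revcomp(src))

    def test_long_tip_retained(self, rng):
        src = self._branchy(rng)
        tip_branch = src[150 - 16 : 150] + random_seq(rng, 2 * 17 + 5)
        reads = tiling_reads(src, 120, 36) * 2 + tiling_reads(tip_branch, 6, 36)
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(reads, params)
        n_before = len(g.nodes)
        dbg.remove_tips(g, params)
        g.validate()
        # the long branch survives (its terminal node is >= 2k of sequence)
        assert any(
            len(n.seq) >= 2 * 17 and n.mean_cov < 2.5 for n in g.nodes.values()
        ) or len(g.nodes) == n_before

    def test_branchless_graph_unchanged(self, rng):
        src = random_source(rng, 200)
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(tiling_reads(src, 80, 36), params)
        seqs_before = sorted(n.seq for n in g.nodes.values())
        dbg.remove_tips(g, params)
        assert sorted(n.seq for n in g.nodes.values()) == seqs_before


class TestCollapseBubbles:
    def test_single_substitution_bubble_majority_wins(self, rng):
        src = random_source(rng, 300)
        variant = src[:150] + ("A" if src[150] != "A" else "C") + src[151:]
        reads = tiling_reads(src, 270, 36) + tiling_reads(variant, 30, 36)
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(reads, params)
        dbg.remove_tips(g, params)
        dbg.collapse_bubbles(g, params)
        g.validate()
        assert len(g.nodes) == 1
        (node,) = g.nodes.values()
        assert node.seq in (src, revcomp(src))  # majority base kept

    def test_dissimilar_paths_retained(self, rng):
        # two haplotypes sharing ends but with an unrelated 80-bp middle
        left, right = random_seq(rng, 100), random_seq(rng, 100)
        h1 = left + random_seq(rng, 80) + right
        h2 = left + random_seq(rng, 80) + right
        reads = tiling_reads(h1, 120, 36) + tiling_reads(h2, 120, 36)
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(reads, params)
        dbg.remove_tips(g, params)
        n_before = len(g.nodes)
        dbg.collapse_bubbles(g, params)
        g.validate()
        assert len(g.nodes) == n_before  # identity ~0.5 < 0.8: no collapse

    def test_bubble_free_graph_idempotent(self, rng):
        src = random_source(rng, 250)
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(tiling_reads(src, 100, 36), params)
        seqs = sorted(n.seq for n in g.nodes.values())
        dbg.collapse_bubbles(g, params)
        assert sorted(n.seq for n in g.nodes.values()) == seqs


class TestRemoveLowCoverage:
    def test_low_coverage_node_removed(self, rng):
        src = random_source(rng, 100, k=13)
        params = dbg.AssemblyParams(k=17, min_node_coverage=2.0)
        g = dbg.build_graph(tiling_reads(src, 4, 36), params)
        assert all(n.mean_cov < 2.0 for n in g.nodes.values())
        dbg.remove_low_coverage(g, params)
        assert len(g.nodes) == 0

    def test_cutoff_zero_is_a_no_op(self, rng):
        src = random_source(rng, 200)
        params = dbg.AssemblyParams(k=17, min_node_coverage=0.0)
        g = dbg.build_graph(tiling_reads(src, 50, 36), params)
        n = len(g.nodes)
        dbg.remove_low_coverage(g, params)
        assert len(g.nodes) == n

    def test_error_flanked_contig_survives(self, rng):
        src = random_source(rng, 300)
        reads = tiling_reads(src, 250, 36)
        reads += [src[0:36]] * 2  # make the true start kmer outweigh errors
        # a read with an error at its first base creates a cov-1 flank node
        bad = "T" + src[1:36] if src[0] != "T" else "G" + src[1:36]
        reads += [bad]
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(reads, params)
        dbg.remove_tips(g, params)
        dbg.collapse_bubbles(g, params)
        dbg.remove_low_coverage(g, params)
        g.validate()
        assert len(g.nodes) == 1
        (node,) = g.nodes.values()
        assert node.seq in (src, revcomp(src))


class TestExtractChiptigs:
    def test_length_threshold_boundary(self, rng):
        src = random_seq(rng, 49)
        params = dbg.AssemblyParams(k=17, min_node_coverage=0.0, min_output_length=50)
        g = dbg.build_graph(tiling_reads(src, 20, 36), params)
        assert dbg.extract_chiptigs(g, params) == []

    def test_known_source_reported_canonically(self, rng):
        src = random_source(rng, 300)
        params = dbg.AssemblyParams(k=17)
        tigs = dbg.assemble(tiling_reads(src, 250, 36), params)
        assert len(tigs) == 1
        assert tigs[0].sequence == min(src, revcomp(src))
        assert tigs[0].id == "dbg_1"
        assert tigs[0].mean_coverage == pytest.approx(
            sum(1 for _ in range(250)) * 20 / 284, rel=0.01
        )

    def test_empty_graph_empty_output(self):
        params = dbg.AssemblyParams(k=17)
        g = dbg.DBGraph(17)
        assert dbg.extract_chiptigs(g, params) == []

    def test_ids_in_decreasing_coverage_order(self, rng):
        deep = random_source(rng, 120)
        shallow = random_source(rng, 120)
        reads = tiling_reads(deep, 100, 36) + tiling_reads(shallow, 30, 36)
        tigs = dbg.assemble(reads, dbg.AssemblyParams(k=17))
        assert [t.id for t in tigs] == ["dbg_1", "dbg_2"]
        assert tigs[0].mean_coverage > tigs[1].mean_coverage


class TestInvariants:
    def test_determinism(self, rng):
        src = random_source(rng, 400)
        reads = tiling_reads(src, 200, 36, rng, error_rate=0.01)
        t1 = dbg.assemble(reads, dbg.AssemblyParams(k=17))
        t2 = dbg.assemble(list(reads), dbg.AssemblyParams(k=17))
        assert [(t.id, t.sequence) for t in t1] == [(t.id, t.sequence) for t in t2]

    def test_twin_symmetry_preserved_across_stages(self, rng):
        src = random_source(rng, 500)
        reads = tiling_reads(src, 400, 36, rng, error_rate=0.01)
        params = dbg.AssemblyParams(k=17)
        g = dbg.build_graph(reads, params)
        g.validate()
        dbg.remove_tips(g, params)
        g.validate()
        dbg.collapse_bubbles(g, params)
        g.validate()
        dbg.remove_low_coverage(g, params)
        g.validate()
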