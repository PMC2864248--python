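"""Contig adjacency graph: link extraction, multiplicities, traversal."""

import numpy as np
import pytest

from _oracles import canon, oracle_verdict
from finishkit.core_io import FormatError, LinkRecord, PafAlignment, SequenceRecord
from finishkit.contig_graph import (
    build_graph,
    connecting_paths,
    estimate_multiplicities,
    find_unique_traversal,
    links_from_alignments,
    reconstruct_sequence,
    ContigNode,
)
from finishkit.simulate import (
    GenomeSpec,
    RepeatSpec,
    derive_contigs,
    simulate_genome,
    simulate_links,
)


def paf(read, rlen, rs, re_, strand, contig, clen, cs, ce):
    return PafAlignment(read, rlen, rs, re_, strand, contig, clen, cs, ce, 0, 0, 60)


class TestLinksFromAlignments:
    CONTIGS = {"c1": 1000, "c2": 800}

    def test_forward_forward_gap(self):
        alns = [
            paf("r", 120, 0, 50, "+", "c1", 1000, 950, 1000),
            paf("r", 120, 60, 120, "+", "c2", 800, 0, 60),
        ]
        (lk,) = links_from_alignments(alns, self.CONTIGS, min_support=1)
        assert {(lk.contig_a, lk.end_a), (lk.contig_b, lk.end_b)} == {("c1", "E"), ("c2", "B")}
        assert lk.offset_bp == 10

    def test_reverse_second_contig(self):
        alns = [
            paf("r", 120, 0, 50, "+", "c1", 1000, 950, 1000),
            paf("r", 120, 60, 120, "-", "c2", 800, 740, 800),
        ]
        (lk,) = links_from_alignments(alns, self.CONTIGS, min_support=1)
        assert {(lk.contig_a, lk.end_a), (lk.contig_b, lk.end_b)} == {("c1", "E"), ("c2", "E")}

    def test_median_offset_and_support(self):
        alns = []
        for i, off in enumerate((-20, -22, -18)):
            alns += [
                paf(f"r{i}", 200, 0, 100, "+", "c1", 1000, 900 + off, 1000 + off),
                paf(f"r{i}", 200, 100 + off, 200 + off, "+", "c2", 800, 0, 100),
            ]
        # arrange reads so read gap equals the overlap offset
        alns = [
            a for i, off in enumerate((-20, -22, -18))
            for a in (
                paf(f"r{i}", 200, 0, 100, "+", "c1", 1000, 900, 1000),
                paf(f"r{i}", 200, 100 + off, 200 + off, "+", "c2", 800, 0, 100),
            )
        ]
        out = links_from_alignments(alns, self.CONTIGS, min_support=2)
        assert len(out) == 1
        assert out[0].support == 3
        assert out[0].offset_bp == -20

    def test_min_support_filters(self):
        alns = [
            paf("r", 120, 0, 50, "+", "c1", 1000, 950, 1000),
            paf("r", 120, 60, 120, "+", "c2", 800, 0, 60),
        ]
        assert links_from_alignments(alns, self.CONTIGS, min_support=2) == []

    def test_alignment_far_from_end_skipped(self):
        alns = [
            paf("r", 120, 0, 50, "+", "c1", 1000, 400, 450),
            paf("r", 120, 60, 120, "+", "c2", 800, 0, 60),
        ]
        assert links_from_alignments(alns, self.CONTIGS, min_support=1) == []

    def test_unknown_contig_rejected(self):
        with pytest.raises(FormatError):
            links_from_alignments(
                [paf("r", 10, 0, 10, "+", "nope", 100, 0, 10)], self.CONTIGS
            )


class TestMultiplicities:
    def test_near_unit_ratios(self):
        nodes = {c: ContigNode(c, 20_000) for c in "abc"}
        estimate_multiplicities(nodes, {"a": 20.0, "b": 21.0, "c": 19.0})
        assert all(n.multiplicity == 1 for n in nodes.values())

    def test_rounding_to_three_copies(self):
        nodes = {
            "long1": ContigNode("long1", 50_000),
            "long2": ContigNode("long2", 50_000),
            "rep": ContigNode("rep", 4_000),
        }
        estimate_multiplicities(nodes, {"long1": 20.0, "long2": 20.0, "rep": 61.0})
        assert nodes["rep"].multiplicity == 3

    def test_floor_at_one(self):
        nodes = {"long": ContigNode("long", 50_000), "low": ContigNode("low", 9_000)}
        estimate_multiplicities(nodes, {"long": 20.0, "low": 5.0})
        assert nodes["low"].multiplicity == 1

    def test_missing_coverage_entry_rejected(self):
        nodes = {"a": ContigNode("a", 20_000)}
        with pytest.raises(FormatError):
            estimate_multiplicities(nodes, {})


class TestBuildGraph:
    def test_chain_aggregation_and_threshold(self):
        lengths = {"a": 12_000, "b": 15_000, "c": 11_000}
        cov = {k: 20.0 for k in lengths}
        links = [
            LinkRecord("a", "E", "b", "B", 1, 0),
            LinkRecord("b", "B", "a", "E", 2, 0),  # duplicate pair, other order
            LinkRecord("b", "E", "c", "B", 1, 0),
        ]
        g = build_graph(lengths, links, cov, min_support=2)
        assert len(g.edges) == 1  # a-b aggregated to support 3; b-c filtered
        assert g.edges[0].support == 3

    def test_min_support_monotone(self):
        lengths = {"a": 12_000, "b": 15_000}
        cov = {k: 20.0 for k in lengths}
        links = [LinkRecord("a", "E", "b", "B", s, 0) for s in (1, 1, 1)]
        edge_counts = [
            len(build_graph(lengths, links, cov, min_support=ms).edges)
            for ms in (1, 2, 3, 4)
        ]
        assert edge_counts == sorted(edge_counts, reverse=True)

    def test_unknown_contig_in_link_rejected(self):
        with pytest.raises(FormatError):
            build_graph({"a": 1000}, [LinkRecord("a", "E", "zz", "B", 3, 0)], {"a": 20.0})


class TestTraversal:
    def test_linear_chain_unique(self):
        lengths = {"A": 12_000, "B": 15_000, "C": 11_000}
        cov = {k: 20.0 for k in lengths}
        links = [LinkRecord("A", "E", "B", "B", 3, 0), LinkRecord("B", "E", "C", "B", 3, 0)]
        tr = find_unique_traversal(build_graph(lengths, links, cov))
        assert tr.verdict == "unique" and tr.topology == "linear"
        assert canon(tr.walk, False) == canon([("A", "+"), ("B", "+"), ("C", "+")], False)

    def test_two_copy_repeat_unique(self, two_copy_repeat_graph):
        tr = find_unique_traversal(two_copy_repeat_graph)
        assert tr.verdict == "unique" and tr.topology == "circular"
        expected = [("U1", "+"), ("R", "+"), ("U2", "+"), ("R", "+")]
        assert canon(tr.walk, True) == canon(expected, True)

    def test_three_copy_repeat_multiple(self, three_copy_repeat_graph):
        assert find_unique_traversal(three_copy_repeat_graph).verdict == "multiple"

    def test_degree_violation_inconsistent(self):
        lengths = {"a": 12_000, "b": 15_000, "c": 30_000}
        cov = {"a": 20.0, "b": 61.0, "c": 20.0}  # b looks 3-copy but degree 1
        links = [
            LinkRecord("a", "E", "b", "B", 3, 0),
            LinkRecord("b", "E", "c", "B", 3, 0),
            LinkRecord("c", "E", "a", "B", 3, 0),
        ]
        g = build_graph(lengths, links, cov)
        assert g.nodes["b"].multiplicity == 3
        assert find_unique_traversal(g).verdict == "inconsistent"

    def test_disconnected_graph_none(self):
        lengths = {"a": 12_000, "b": 15_000, "c": 11_000, "d": 9_000}
        cov = {k: 20.0 for k in lengths}
        links = [LinkRecord("a", "E", "b", "B", 3, 0), LinkRecord("c", "E", "d", "B", 3, 0)]
        assert find_unique_traversal(build_graph(lengths, links, cov)).verdict == "none"

    def test_budget_exhaustion_undetermined(self, three_copy_repeat_graph):
        tr = find_unique_traversal(three_copy_repeat_graph, max_steps=2)
        assert tr.verdict == "undetermined"


def random_walk_graph(rng):
    """A random circular genome walk and its induced contig-end graph."""
    n_contigs = int(rng.integers(2, 8))
    ids = [f"c{i}" for i in range(n_contigs)]
    total = int(rng.integers(n_contigs, 13))
    walk = ids.copy()
    walk += [ids[int(rng.integers(0, n_contigs))] for _ in range(total - n_contigs)]
    rng.shuffle(walk)
    orients = ["+" if rng.random() < 0.7 else "-" for _ in walk]
    mult = {c: walk.count(c) for c in ids}
    edges = set()
    m = len(walk)
    ok = True
    for i in range(m):
        a, oa = walk[i], orients[i]
        b, ob = walk[(i + 1) % m], orients[(i + 1) % m]
        ea = ("E" if oa == "+" else "B")
        eb = ("B" if ob == "+" else "E")
        key = tuple(sorted([(a, ea), (b, eb)]))
        if key[0] == key[1] or key in edges:
            ok = False
            break
        edges.add(key)
    if not ok:
        return None
    return mult, [tuple(e) for e in sorted(edges)]


class TestTraversalAgainstOracle:
    def test_agrees_with_exhaustive_enumeration(self):
        """Verdicts (and unique walks) match a brute-force walk enumerator
        on random walk-induced graphs, including randomly damaged ones."""
        rng = np.random.default_rng(777)
        checked = 0
        while checked < 40:
            made = random_walk_graph(rng)
            if made is None:
                continue
            mult, edges = made
            if rng.random() < 0.3 and len(edges) > 2:
                edges = edges[: len(edges) - 1]  # damage: drop an edge
            lengths = {c: 10_000 for c in mult}
            links = [LinkRecord(a[0], a[1], b[0], b[1], 3, 0) for a, b in edges]
            cov = {c: 20.0 * m for c, m in mult.items()}
            g = build_graph(lengths, links, cov)
            for c, n in g.nodes.items():
                n.multiplicity = mult[c]  # pin truth; depth inference has its own tests
            verdict, walks = oracle_verdict(mult, edges)
            tr = find_unique_traversal(g)
            assert tr.verdict == verdict, (mult, edges, tr.verdict, verdict)
            if verdict == "unique":
                assert canon(tr.walk, tr.topology == "circular") == next(iter(walks))
            checked += 1


class TestReconstruct:
    def _traversal(self, walk, offsets, topology="linear"):
        from finishkit.contig_graph import Traversal

        return Traversal("unique", walk, topology, offsets)

    def test_exact_overlap_merge(self):
        contigs = {"c1": "AAAC", "c2": "ACGG"}
        tr = self._traversal([("c1", "+"), ("c2", "+")], [-2])
        assert reconstruct_sequence(tr, contigs).seq == "AAACGG"

    def test_positive_offset_n_fill(self):
        contigs = {"c1": "AAAC", "c2": "ACGG"}
        tr = self._traversal([("c1", "+"), ("c2", "+")], [3])
        assert reconstruct_sequence(tr, contigs).seq == "AAACNNNACGG"

    def test_disagreeing_overlap_rejected(self):
        contigs = {"c1": "AAAA", "c2": "GGGG"}
        tr = self._traversal([("c1", "+"), ("c2", "+")], [-3])
        with pytest.raises(ValueError, match="identity"):
            reconstruct_sequence(tr, contigs)

    def test_length_identity(self):
        contigs = {"c1": "A" * 50, "c2": "ACGT" * 10, "c3": "G" * 30}
        tr = self._traversal([("c1", "+"), ("c2", "-"), ("c3", "+")], [5, 0])
        rec = reconstruct_sequence(tr, contigs)
        assert len(rec.seq) == 50 + 40 + 30 + 5

    @pytest.mark.parametrize("seed", [3, 11])
    def test_simulated_circular_round_trip(self, seed):
        """Graph + unique traversal reproduces a simulated genome exactly
        up to rotation and reverse complement."""
        from finishkit.core_io import revcomp

        spec = GenomeSpec(
            length=150_000, topology="circular",
            repeats=[RepeatSpec("R1", 4000, 2)], seed=seed,
            repeat_orientation="forward",
        )
        genome, layout = simulate_genome(spec)
        contigs, coverage, true_links = derive_contigs(genome, layout, seed=seed)
        links = simulate_links(true_links, mean_support=5, noise_links=4, seed=seed)
        g = build_graph(contigs, links, coverage, min_support=2)
        tr = find_unique_traversal(g)
        assert tr.verdict == "unique"
        rec = reconstruct_sequence(tr, contigs)
        assert len(rec.seq) == len(genome.seq)
        doubled = genome.seq + genome.seq
        assert rec.seq in doubled or revcomp(rec.seq) in doubled


class TestConnectingPaths:
    def test_direct_edge(self, two_copy_repeat_graph):
        paths = connecting_paths(two_copy_repeat_graph, ("U1", "E"), ("R", "B"), 10_000)
        assert any(p.members == [] and p.implied_length == 0 for p in paths)

    def test_single_repeat_path_length(self, two_copy_repeat_graph):
        paths = connecting_paths(two_copy_repeat_graph, ("U1", "E"), ("U2", "B"), 10_000)
        assert [p.members for p in paths] == [[("R", "+")]]
        assert paths[0].implied_length == 3000

    def test_budget_filters_all(self, two_copy_repeat_graph):
        paths = connecting_paths(two_copy_repeat_graph, ("U1", "E"), ("U2", "B"), 100)
        assert list(paths) == []

    def test_multiplicity_bounds_usage(self, three_copy_repeat_graph):
        # U1.E -> U1.B around the circle uses R three times at most
        paths = connecting_paths(
            three_copy_repeat_graph, ("U1", "E"), ("U1", "B"), 200_000, max_paths=1000
        )
        for p in paths:
            uses = [m[0] for m in p.members].count("R")
            assert uses <= 3
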