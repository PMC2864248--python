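"""Scaffold validation, gap closure, GC matching, PCR planning."""

import json

import pytest

from finishkit.core_io import LinkRecord, Scaffold, ScaffoldPart
from finishkit.contig_graph import build_graph
from finishkit.finishing import (
    close_gaps_in_silico,
    estimate_experiment_count,
    finishing_report,
    gc_end_match,
    place_unplaced_by_links,
    report_text,
    round_one_sig,
    validate_adjacencies,
)
from finishkit.simulate import (
    GcIsland,
    GenomeSpec,
    RepeatSpec,
    derive_contigs,
    simulate_genome,
)


def graph_from(lengths, links, mult=None):
    cov = {c: 20.0 * (mult or {}).get(c, 1) for c in lengths}
    g = build_graph(lengths, links, cov, min_support=1)
    for c, n in g.nodes.items():
        n.multiplicity = (mult or {}).get(c, 1)
    return g


def scaffold_of(parts, gaps):
    return Scaffold(id="s", parts=[ScaffoldPart(*p) for p in parts], gaps=gaps)


class TestValidate:
    def test_direct_edge(self):
        g = graph_from({"a": 20_000, "b": 20_000},
                       [LinkRecord("a", "E", "b", "B", 3, 0)])
        sc = scaffold_of([("a", 20_000, "+"), ("b", 20_000, "+")], [100])
        (v,) = validate_adjacencies(sc, g)
        assert v.verdict == "direct"

    def test_path_through_repeat_with_length_agreement(self):
        g = graph_from(
            {"a": 20_000, "r": 5_000, "b": 20_000},
            [LinkRecord("a", "E", "r", "B", 3, 0), LinkRecord("r", "E", "b", "B", 3, 0)],
        )
        sc = scaffold_of([("a", 20_000, "+"), ("b", 20_000, "+")], [5_200])
        (v,) = validate_adjacencies(sc, g)
        assert v.verdict == "path"
        assert v.best_path.members == [("r", "+")]
        assert v.length_agreement == 200

    def test_no_path_within_budget(self):
        g = graph_from({"a": 20_000, "b": 20_000, "z": 90_000},
                       [LinkRecord("a", "E", "z", "B", 3, 0),
                        LinkRecord("z", "E", "b", "B", 3, 0)])
        sc = scaffold_of([("a", 20_000, "+"), ("b", 20_000, "+")], [1_000])
        (v,) = validate_adjacencies(sc, g)
        assert v.verdict == "none"  # the 90 kbp detour exceeds gap + tol

    def test_orientation_aware_ends(self):
        # b placed in reverse: the facing end of b is its E end
        g = graph_from({"a": 20_000, "b": 20_000},
                       [LinkRecord("a", "E", "b", "E", 3, 0)])
        sc = scaffold_of([("a", 20_000, "+"), ("b", 20_000, "-")], [0])
        (v,) = validate_adjacencies(sc, g)
        assert v.verdict == "direct"


class TestAugment:
    def _gap_graph(self, extra_links=(), mult=None):
        lengths = {"L": 30_000, "R": 30_000, "s": 4_000}
        links = [
            LinkRecord("L", "E", "s", "B", 3, 0),
            LinkRecord("s", "E", "R", "B", 3, 0),
            *extra_links,
        ]
        return graph_from(lengths, links, mult)

    def test_small_contig_inserted_into_its_gap(self):
        g = self._gap_graph()
        sc = scaffold_of([("L", 30_000, "+"), ("R", 30_000, "+")], [4_500])
        out = place_unplaced_by_links(sc, g, ["s"])
        assert [p.contig_id for p in out.parts] == ["L", "s", "R"]

    def test_multi_gap_candidate_with_multiplicity_one_stays_out(self):
        lengths = {"L1": 30_000, "R1": 30_000, "L2": 30_000, "R2": 30_000, "s": 4_000}
        links = [
            LinkRecord("L1", "E", "s", "B", 3, 0), LinkRecord("s", "E", "R1", "B", 3, 0),
            LinkRecord("L2", "E", "s", "B", 3, 0), LinkRecord("s", "E", "R2", "B", 3, 0),
        ]
        g = graph_from(lengths, links)
        sc = scaffold_of(
            [("L1", 30_000, "+"), ("R1", 30_000, "+"), ("L2", 30_000, "+"), ("R2", 30_000, "+")],
            [4_500, 200_000, 4_500],
        )
        out = place_unplaced_by_links(sc, g, ["s"])
        assert [p.contig_id for p in out.parts] == ["L1", "R1", "L2", "R2"]

    def test_high_multiplicity_repeat_fills_every_consistent_gap(self):
        """An rRNA-operon-like 6-copy contig linking 6 gaps fills all of them."""
        lengths = {"rrn": 5_000}
        parts, gaps, links = [], [], []
        for i in range(6):
            l, r = f"L{i}", f"R{i}"
            lengths[l] = lengths[r] = 30_000
            parts += [(l, 30_000, "+"), (r, 30_000, "+")]
            links += [LinkRecord(l, "E", "rrn", "B", 3, 0),
                      LinkRecord("rrn", "E", r, "B", 3, 0)]
            gaps += [5_500, 100_000]
        gaps.pop()
        g = graph_from(lengths, links, mult={"rrn": 6})
        sc = scaffold_of(parts, gaps)
        out = place_unplaced_by_links(sc, g, ["rrn"])
        assert sum(1 for p in out.parts if p.contig_id == "rrn") == 6


class TestCloseGaps:
    def _setup(self, mult_r=1, two_paths=False):
        lengths = {"a": 30_000, "r": 5_000, "b": 30_000}
        links = [
            LinkRecord("a", "E", "r", "B", 3, 0),
            LinkRecord("r", "E", "b", "B", 3, 0),
        ]
        if two_paths:
            lengths["q"] = 5_000
            links += [LinkRecord("a", "E", "q", "B", 3, 0),
                      LinkRecord("q", "E", "b", "B", 3, 0)]
        g = graph_from(lengths, links, {"r": mult_r})
        sc = scaffold_of([("a", 30_000, "+"), ("b", 30_000, "+")], [5_200])
        return g, sc

    def test_unique_agreeing_path_closes(self):
        g, sc = self._setup()
        closures, updated = close_gaps_in_silico(sc, g)
        assert closures[0].status == "closed"
        assert closures[0].inserted == [("r", "+")]
        assert [p.contig_id for p in updated.parts] == ["a", "r", "b"]

    def test_two_agreeing_paths_stay_open(self):
        g, sc = self._setup(two_paths=True)
        closures, updated = close_gaps_in_silico(sc, g)
        assert closures[0].status == "open"
        assert [p.contig_id for p in updated.parts] == ["a", "b"]

    def test_multiplicity_conservation_across_closures(self):
        # two gaps both needing r, but r is single-copy: only one closes
        lengths = {"a": 30_000, "r": 5_000, "b": 30_000, "c": 30_000}
        links = [
            LinkRecord("a", "E", "r", "B", 3, 0), LinkRecord("r", "E", "b", "B", 3, 0),
            LinkRecord("b", "E", "r", "B", 3, 0), LinkRecord("r", "E", "c", "B", 3, 0),
        ]
        g = graph_from(lengths, links, {"r": 1})
        sc = scaffold_of([("a", 30_000, "+"), ("b", 30_000, "+"), ("c", 30_000, "+")],
                         [5_100, 5_200])
        closures, updated = close_gaps_in_silico(sc, g)
        statuses = sorted(c.status for c in closures)
        assert statuses == ["closed", "open"]
        assert sum(1 for p in updated.parts if p.contig_id == "r") == 1

    def test_closure_preserves_flanking_order(self):
        g, sc = self._setup()
        _, updated = close_gaps_in_silico(sc, g)
        placed = [p.contig_id for p in updated.parts]
        assert placed.index("a") < placed.index("b")


class TestGcMatch:
    def test_matching_gc_ranked_first(self):
        seqs = {
            "L": "AT" * 2000 + "ATAT" * 250,   # flank GC 0
            "R": "AT" * 2000,
            "good": "AT" * 6000,               # GC 0 ends
            "bad": "GC" * 6000,                # GC 1 ends
        }
        sc = scaffold_of([("L", len(seqs["L"]), "+"), ("R", len(seqs["R"]), "+")], [12_000])
        ranked = gc_end_match(sc, seqs, ["good", "bad"], w=1000, min_len=10_000)
        lst = ranked[("L", "R")]
        assert [c.contig_id for c in lst] == ["good", "bad"]
        assert lst[0].score == pytest.approx(0.0)
        assert 0 <= lst[-1].score <= 2

    def test_short_candidates_excluded(self):
        seqs = {"L": "AT" * 2000, "R": "AT" * 2000, "tiny": "AT" * 100}
        sc = scaffold_of([("L", 4_000, "+"), ("R", 4_000, "+")], [1_000])
        ranked = gc_end_match(sc, seqs, ["tiny"], w=1000, min_len=10_000)
        assert ranked[("L", "R")] == []

    def test_uniform_gc_ties_break_by_id(self):
        seqs = {"L": "ATGC" * 3000, "R": "ATGC" * 3000,
                "x2": "ATGC" * 3000, "x1": "ATGC" * 3000}
        sc = scaffold_of([("L", 12_000, "+"), ("R", 12_000, "+")], [12_000])
        ranked = gc_end_match(sc, seqs, ["x2", "x1"], w=1000, min_len=10_000)
        assert [c.contig_id for c in ranked[("L", "R")]] == ["x1", "x2"]

    def test_island_filler_top_ranked_on_simulated_genome(self):
        """A GC-distinct island spanning a gap pulls its filler to rank 1."""
        top = 0
        for seed in range(10):
            reps = [RepeatSpec("R", 2000, 2, positions=[40_000, 54_000],
                               orientations=["+", "+"]),
                    RepeatSpec("Q", 2000, 2, positions=[90_000, 104_000],
                               orientations=["+", "+"])]
            spec = GenomeSpec(length=140_000, gc=0.40, topology="linear",
                              repeats=reps,
                              gc_islands=[GcIsland(18_000, 0.60, position=39_000)],
                              seed=seed)
            genome, layout = simulate_genome(spec)
            contigs, coverage, links = derive_contigs(genome, layout, seed=seed)
            g = build_graph(contigs, links, coverage, min_support=1)
            seqs = {c.id: c.seq for c in contigs}
            sc = scaffold_of([("u1", 40_000, "+"), ("u3", 34_000, "+")], [16_000])
            ranked = gc_end_match(sc, seqs, ["u2", "u4", "rep_R", "rep_Q"], g)
            if ranked[("u1", "u3")][0].contig_id == "u2":
                top += 1
        assert top >= 9


class TestExperimentPlan:
    def test_unordered_is_n_squared_with_sig_fig(self):
        plan = estimate_experiment_count(59, "unordered")
        assert plan.estimated_experiments == 3481
        assert plan.one_sig_fig == 3000
        assert plan.pairwise_unordered == 59 * 58 // 2

    def test_scaffolded_counts_gaps(self):
        assert estimate_experiment_count(59, "scaffolded").estimated_experiments == 58
        assert estimate_experiment_count(
            59, "scaffolded", topology="circular").estimated_experiments == 59
        assert estimate_experiment_count(1, "scaffolded").estimated_experiments == 0

    def test_scaffolding_always_saves_experiments(self):
        for n in range(2, 200):
            un = estimate_experiment_count(n, "unordered").estimated_experiments
            sc = estimate_experiment_count(n, "scaffolded").estimated_experiments
            assert un / max(sc, 1) >= n

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            estimate_experiment_count(0, "unordered")

    def test_plan_lists_facing_end_pairs(self):
        sc = scaffold_of([("a", 10_000, "+"), ("b", 10_000, "-")], [100])
        plan = estimate_experiment_count(2, "scaffolded", scaffold=sc)
        assert plan.gap_end_pairs == [(("a", "E"), ("b", "E"))]

    def test_round_one_sig(self):
        assert round_one_sig(3481) == 3000
        assert round_one_sig(58) == 60
        assert round_one_sig(0) == 0


class TestReport:
    def test_empty_scaffold_report_valid_json(self):
        doc = finishing_report(Scaffold(id="s"))
        parsed = json.loads(json.dumps(doc))
        assert parsed["scaffold"]["n_contigs"] == 0
        assert report_text(parsed)

    def test_totals_match_sections(self):
        g = graph_from({"a": 30_000, "r": 5_000, "b": 30_000},
                       [LinkRecord("a", "E", "r", "B", 3, 0),
                        LinkRecord("r", "E", "b", "B", 3, 0)])
        sc = scaffold_of([("a", 30_000, "+"), ("b", 30_000, "+")], [5_200])
        verdicts = validate_adjacencies(sc, g)
        closures, updated = close_gaps_in_silico(sc, g)
        doc = finishing_report(updated, verdicts, closures)
        assert doc["totals"]["gaps_closed"] == sum(
            1 for c in doc["closures"] if c["status"] == "closed")
        assert "r" in [m[0] for c in doc["closures"] for m in c["inserted"]]
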