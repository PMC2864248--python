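"""Scaffold validation, in-silico gap closure, and experiment planning.

A map-derived scaffold orders contigs genome-wide but says nothing about
the sequence inside its gaps.  The contig adjacency graph fills that role:
facing ends of consecutive scaffold contigs can be checked for a direct
spanning edge, connected through paths of intermediate (often repeat)
contigs, and — when exactly one length-consistent path exists — the gap
can be closed in silico by gluing the intermediate contigs in.

Repeat copy numbers act as a conservation budget: a contig is never used
more times than its estimated multiplicity, and any ambiguity (several
candidate paths, several candidate gaps) leaves the gap open rather than
risking a mis-join.

For gaps that resist graph analysis, candidate fillers are ranked by how
well the GC content of their 1 kbp ends matches the 1 kbp flank ends of
the gap — regional base composition is locally coherent in bacterial
genomes, so a filler native to the gap's neighbourhood tends to match
both flanks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

from .core_io import Scaffold, ScaffoldPart, gc_fraction, revcomp
from .contig_graph import (
    ConnectingPath,
    ContigGraph,
    connecting_paths,
    entry_end,
    exit_end,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyVerdict",
    "GapClosure",
    "GcCandidate",
    "ExperimentPlan",
    "validate_adjacencies",
    "place_unplaced_by_links",
    "close_gaps_in_silico",
    "gc_end_match",
    "estimate_experiment_count",
    "round_one_sig",
    "finishing_report",
]


def _gap_tol(gap: int) -> int:
    return max(5000, int(0.3 * max(gap, 0)))


def _facing_ends(left: ScaffoldPart, right: ScaffoldPart) -> tuple[tuple[str, str], tuple[str, str]]:
    """The two contig ends that face each other across a scaffold gap."""
    return (
        (left.contig_id, exit_end(left.orientation)),
        (right.contig_id, entry_end(right.orientation)),
    )


@dataclass
class AdjacencyVerdict:
    """Graph support for one scaffold junction."""

    gap_id: tuple[str, str]
    verdict: str  # "direct" | "path" | "none"
    best_path: ConnectingPath | None = None
    length_agreement: int | None = None  # |implied - map gap| bp
    map_gap: int = 0


def validate_adjacencies(
    scaffold: Scaffold,
    graph: ContigGraph,
    tol: int | None = None,
) -> list[AdjacencyVerdict]:
    """Check every consecutive scaffold pair against the contig graph.

    Verdict ``direct`` when a single edge joins the facing ends; ``path``
    when a connecting path exists within the gap budget (the best
    length-agreeing path is reported); ``none`` otherwise.  The default
    budget is ``gap + max(5 kbp, 0.3 * gap)``.
    """
    out: list[AdjacencyVerdict] = []
    for i in range(len(scaffold.parts) - 1):
        left, right = scaffold.parts[i], scaffold.parts[i + 1]
        gap = int(scaffold.gaps[i] or 0)
        end_l, end_r = _facing_ends(left, right)
        gid = (left.contig_id, right.contig_id)
        t = tol if tol is not None else _gap_tol(gap)
        if graph.edge_between(end_l, end_r) is not None:
            out.append(AdjacencyVerdict(gid, "direct", None, abs(gap), gap))
            continue
        paths = connecting_paths(graph, end_l, end_r, max_path_bp=gap + t)
        paths = [p for p in paths if p.members]
        if paths:
            best = min(paths, key=lambda p: abs(p.implied_length - gap))
            out.append(
                AdjacencyVerdict(gid, "path", best, abs(best.implied_length - gap), gap)
            )
        else:
            out.append(AdjacencyVerdict(gid, "none", None, None, gap))
    return out


def _remaining_multiplicity(scaffold: Scaffold, graph: ContigGraph) -> dict[str, int]:
    used: dict[str, int] = {}
    for part in scaffold.parts:
        used[part.contig_id] = used.get(part.contig_id, 0) + 1
    return {
        cid: node.multiplicity - used.get(cid, 0)
        for cid, node in graph.nodes.items()
    }


def place_unplaced_by_links(
    scaffold: Scaffold,
    graph: ContigGraph,
    unplaced: list[str],
    tol: int | None = None,
) -> Scaffold:
    """Insert unplaced contigs into gaps both of whose flanks they link to.

    A contig qualifies for a gap when it has edges to both facing flank
    ends with consistent orientation and its implied length fits the gap
    budget.  A contig qualifying for exactly one gap is inserted there; a
    contig qualifying for several gaps is inserted into each only if its
    remaining multiplicity covers them all (the repeat case, e.g. an rRNA
    operon linking many gaps); otherwise it is left unplaced.
    """
    remaining = _remaining_multiplicity(scaffold, graph)
    for cid in unplaced:
        if cid not in graph.nodes:
            raise ValueError(f"unplaced contig {cid!r} not in graph")

    fits: dict[str, list[tuple[int, str, int]]] = {cid: [] for cid in unplaced}
    for i in range(len(scaffold.parts) - 1):
        left, right = scaffold.parts[i], scaffold.parts[i + 1]
        gap = int(scaffold.gaps[i] or 0)
        t = tol if tol is not None else _gap_tol(gap)
        end_l, end_r = _facing_ends(left, right)
        for cid in unplaced:
            node = graph.nodes[cid]
            for orient in ("+", "-"):
                e1 = graph.edge_between(end_l, (cid, entry_end(orient)))
                e2 = graph.edge_between((cid, exit_end(orient)), end_r)
                if e1 is None or e2 is None:
                    continue
                implied = node.length + e1.offset_bp + e2.offset_bp
                if implied <= gap + t:
                    fits[cid].append((i, orient, implied))
                    break

    insertions: dict[int, list[tuple[str, str, int]]] = {}
    for cid, hits in fits.items():
        if not hits:
            continue
        if len(hits) == 1:
            if remaining.get(cid, 0) >= 1:
                i, orient, implied = hits[0]
                insertions.setdefault(i, []).append((cid, orient, implied))
                remaining[cid] -= 1
        elif remaining.get(cid, 0) >= len(hits):
            for i, orient, implied in hits:
                insertions.setdefault(i, []).append((cid, orient, implied))
                remaining[cid] -= 1
        else:
            logger.info(
                "contig %s links %d gaps but multiplicity allows %d; left unplaced",
                cid, len(hits), remaining.get(cid, 0),
            )

    if not insertions:
        return scaffold
    parts: list[ScaffoldPart] = []
    gaps: list[int | None] = []
    for i, part in enumerate(scaffold.parts):
        parts.append(part)
        if i >= len(scaffold.parts) - 1:
            break
        gap = scaffold.gaps[i]
        ins = insertions.get(i, [])
        if not ins:
            gaps.append(gap)
            continue
        # insert one contig per gap (multiple qualifying the same gap would
        # be ambiguous ordering; keep the first, leave the rest unplaced)
        cid, orient, implied = ins[0]
        node = graph.nodes[cid]
        leftover = max(0, int(gap or 0) - implied)
        parts.append(ScaffoldPart(cid, node.length, orient))
        gaps.append(leftover // 2)
        gaps.append(leftover - leftover // 2)
    return Scaffold(
        id=scaffold.id, parts=parts, gaps=gaps, map_id=scaffold.map_id,
        map_length=scaffold.map_length, coverage_frac=scaffold.coverage_frac,
        conflicts=list(scaffold.conflicts),
    )


@dataclass
class GapClosure:
    """Outcome of an in-silico closure attempt on one gap."""

    gap_id: tuple[str, str]
    method: str  # "graph_path" | "direct_edge"
    inserted: list[tuple[str, str]] = field(default_factory=list)
    status: str = "open"
    note: str = ""


def close_gaps_in_silico(
    scaffold: Scaffold,
    graph: ContigGraph,
    max_paths: int = 100,
) -> tuple[list[GapClosure], Scaffold]:
    """Close scaffold gaps through unique, length-consistent graph paths.

    Gaps are processed in ascending size (small gaps close most reliably
    and early closures constrain the multiplicity budget for later ones).
    A gap closes iff exactly one connecting path agrees with the map gap
    within tolerance and every member contig still has multiplicity left;
    closing decrements the budget.  A direct spanning edge closes a gap
    with no inserted sequence.  Anything ambiguous stays open.
    """
    remaining = _remaining_multiplicity(scaffold, graph)
    order = sorted(
        range(len(scaffold.parts) - 1), key=lambda i: int(scaffold.gaps[i] or 0)
    )
    closures: dict[int, GapClosure] = {}
    for i in order:
        left, right = scaffold.parts[i], scaffold.parts[i + 1]
        gap = int(scaffold.gaps[i] or 0)
        t = _gap_tol(gap)
        end_l, end_r = _facing_ends(left, right)
        gid = (left.contig_id, right.contig_id)
        if graph.edge_between(end_l, end_r) is not None:
            closures[i] = GapClosure(gid, "direct_edge", [], "closed", "spanning edge")
            continue
        paths = connecting_paths(graph, end_l, end_r, gap + t, max_paths=max_paths)
        agreeing = [
            p for p in paths if p.members and abs(p.implied_length - gap) <= t
        ]
        if paths.truncated:
            closures[i] = GapClosure(gid, "graph_path", [], "open", "enumeration truncated")
            continue
        if len(agreeing) != 1:
            closures[i] = GapClosure(
                gid, "graph_path", [], "open",
                f"{len(agreeing)} length-agreeing paths",
            )
            continue
        path = agreeing[0]
        need: dict[str, int] = {}
        for cid, _ in path.members:
            need[cid] = need.get(cid, 0) + 1
        if any(remaining.get(cid, 0) < k for cid, k in need.items()):
            closures[i] = GapClosure(
                gid, "graph_path", [], "open", "multiplicity exhausted"
            )
            continue
        for cid, k in need.items():
            remaining[cid] -= k
        closures[i] = GapClosure(gid, "graph_path", list(path.members), "closed")

    parts: list[ScaffoldPart] = []
    gaps: list[int | None] = []
    for i, part in enumerate(scaffold.parts):
        parts.append(part)
        if i >= len(scaffold.parts) - 1:
            break
        cl = closures[i]
        if cl.status != "closed":
            gaps.append(scaffold.gaps[i])
            continue
        if not cl.inserted:
            gaps.append(0)
            continue
        gaps.append(0)
        for cid, orient in cl.inserted:
            parts.append(ScaffoldPart(cid, graph.nodes[cid].length, orient))
            gaps.append(0)
    updated = Scaffold(
        id=scaffold.id, parts=parts, gaps=gaps, map_id=scaffold.map_id,
        map_length=scaffold.map_length, coverage_frac=scaffold.coverage_frac,
        conflicts=list(scaffold.conflicts),
    )
    return [closures[i] for i in sorted(closures)], updated


@dataclass
class GcCandidate:
    """A gap-filler candidate scored by GC match of its two ends."""

    gap_id: tuple[str, str]
    contig_id: str
    orientation: str
    score: float  # |GC(left flank) - GC(near end)| + |GC(right flank) - GC(far end)|


def _end_window(seq: str, which: str, w: int) -> str:
    return seq[-w:] if which == "tail" else seq[:w]


def gc_end_match(
    scaffold: Scaffold,
    sequences: dict[str, str],
    unplaced: list[str],
    graph: ContigGraph | None = None,
    w: int = 1000,
    min_len: int = 10_000,
) -> dict[tuple[str, str], list[GcCandidate]]:
    """Rank unplaced contigs per gap by GC match of 1 kbp contig ends.

    Candidates are unplaced contigs at least ``min_len`` long with
    remaining multiplicity; each is scored in both orientations (best
    kept) as the sum of absolute GC differences between the gap's two
    flank ends and the candidate's corresponding ends.  Windows are
    truncated when a contig is shorter than ``w``; GC is computed over
    unambiguous bases only.
    """
    remaining = (
        _remaining_multiplicity(scaffold, graph) if graph is not None else None
    )
    candidates = [
        cid for cid in unplaced
        if len(sequences[cid]) >= min_len
        and (remaining is None or remaining.get(cid, 0) >= 1)
    ]
    out: dict[tuple[str, str], list[GcCandidate]] = {}
    for i in range(len(scaffold.parts) - 1):
        left, right = scaffold.parts[i], scaffold.parts[i + 1]
        gid = (left.contig_id, right.contig_id)
        lseq = sequences[left.contig_id]
        rseq = sequences[right.contig_id]
        if left.orientation == "-":
            lseq = revcomp(lseq)
        if right.orientation == "-":
            rseq = revcomp(rseq)
        if not lseq or not rseq:
            continue
        gc_left = gc_fraction(_end_window(lseq, "tail", w))
        gc_right = gc_fraction(_end_window(rseq, "head", w))
        ranked: list[GcCandidate] = []
        for cid in candidates:
            seq = sequences[cid]
            best: GcCandidate | None = None
            for orient in ("+", "-"):
                s = seq if orient == "+" else revcomp(seq)
                near = gc_fraction(_end_window(s, "head", w))
                far = gc_fraction(_end_window(s, "tail", w))
                score = abs(gc_left - near) + abs(gc_right - far)
                if best is None or score < best.score:
                    best = GcCandidate(gid, cid, orient, score)
            ranked.append(best)
        ranked.sort(key=lambda c: (c.score, c.contig_id))
        out[gid] = ranked
    return out


@dataclass
class ExperimentPlan:
    """PCR effort estimate for ordering/closing a set of contigs.

    Without a scaffold, ordering n contigs requires testing every ordered
    contig pair — on the order of n^2 experiments; with a genome-wide
    scaffold only one experiment per gap is needed (n - 1 linear, n
    circular).
    """

    mode: str  # "unordered" | "scaffolded"
    n: int
    estimated_experiments: int
    one_sig_fig: int
    pairwise_unordered: int  # n*(n-1)/2, reported alongside n^2
    gap_end_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = field(
        default_factory=list
    )


def round_one_sig(x: int | float) -> int:
    """Round to one significant figure (3481 -> 3000)."""
    if x == 0:
        return 0
    return int(float(f"{float(x):.0e}"))


def estimate_experiment_count(
    n: int,
    mode: str,
    topology: str = "linear",
    scaffold: Scaffold | None = None,
) -> ExperimentPlan:
    """Estimate the PCR experiments needed to order/close ``n`` contigs.

    ``unordered`` uses the n-squared all-pairs figure (the pairwise count
    n(n-1)/2 is reported alongside); ``scaffolded`` counts one experiment
    per scaffold gap.  The one-significant-figure rounding of the estimate
    is included for order-of-magnitude reporting.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "unordered":
        est = n * n
        pairs: list = []
    elif mode == "scaffolded":
        if scaffold is not None:
            junctions = range(len(scaffold.parts) - 1)
            pairs = [
                _facing_ends(scaffold.parts[i], scaffold.parts[i + 1])
                for i in junctions
            ]
            est = len(pairs)
        else:
            est = n if topology == "circular" else n - 1
            pairs = []
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ExperimentPlan(
        mode=mode,
        n=n,
        estimated_experiments=est,
        one_sig_fig=round_one_sig(est),
        pairwise_unordered=n * (n - 1) // 2,
        gap_end_pairs=pairs,
    )


def finishing_report(
    scaffold: Scaffold,
    verdicts: list[AdjacencyVerdict] | None = None,
    closures: list[GapClosure] | None = None,
    candidates: dict[tuple[str, str], list[GcCandidate]] | None = None,
    plan: ExperimentPlan | None = None,
    unplaced: list[str] | None = None,
) -> dict:
    """Machine-readable (JSON-serializable) summary of one finishing run.

    Use ``json.dumps`` for the file form and :func:`report_text` for the
    human-readable rendering.
    """
    verdicts = verdicts or []
    closures = closures or []
    candidates = candidates or {}
    doc = {
        "scaffold": {
            "id": scaffold.id,
            "n_contigs": len(scaffold.parts),
            "n_gaps": max(0, len(scaffold.parts) - 1),
            "span_bp": scaffold.span if scaffold.parts else 0,
            "map_id": scaffold.map_id,
            "map_coverage_pct": (
                round(100.0 * scaffold.coverage_frac, 1)
                if scaffold.coverage_frac is not None else None
            ),
            "contigs": [
                {"id": p.contig_id, "length": p.length, "orientation": p.orientation}
                for p in scaffold.parts
            ],
            "conflicts": list(scaffold.conflicts),
        },
        "unplaced": sorted(unplaced or []),
        "adjacency": [
            {
                "gap": list(v.gap_id),
                "verdict": v.verdict,
                "map_gap_bp": v.map_gap,
                "length_agreement_bp": v.length_agreement,
                "path": [list(m) for m in v.best_path.members] if v.best_path else None,
            }
            for v in verdicts
        ],
        "closures": [
            {
                "gap": list(c.gap_id),
                "method": c.method,
                "status": c.status,
                "inserted": [list(m) for m in c.inserted],
                "note": c.note,
            }
            for c in closures
        ],
        "gc_candidates": {
            "|".join(gid): [
                {"contig": c.contig_id, "orientation": c.orientation,
                 "score": round(c.score, 4)}
                for c in ranked[:5]
            ]
            for gid, ranked in candidates.items()
        },
        "experiments": asdict(plan) if plan else None,
        "totals": {
            "gaps_closed": sum(1 for c in closures if c.status == "closed"),
            "gaps_open": sum(1 for c in closures if c.status != "closed"),
            "direct_adjacencies": sum(1 for v in verdicts if v.verdict == "direct"),
        },
    }
    # self-check: the document must survive a JSON round trip
    json.loads(json.dumps(doc))
    return doc


def report_text(doc: dict) -> str:
    """Render a finishing report document as human-readable text."""
    sc = doc["scaffold"]
    lines = [
        f"Scaffold {sc['id']}: {sc['n_contigs']} contigs, {sc['n_gaps']} gaps, "
        f"{sc['span_bp']} bp",
    ]
    if sc.get("map_coverage_pct") is not None:
        lines.append(f"  map {sc['map_id']}: {sc['map_coverage_pct']}% covered")
    if doc["unplaced"]:
        lines.append(f"  unplaced contigs: {', '.join(doc['unplaced'])}")
    for v in doc["adjacency"]:
        lines.append(
            f"  junction {v['gap'][0]} -> {v['gap'][1]}: {v['verdict']}"
            + (f" (path {v['path']})" if v.get("path") else "")
        )
    for c in doc["closures"]:
        lines.append(
            f"  gap {c['gap'][0]} -> {c['gap'][1]}: {c['status']} [{c['method']}]"
            + (f" inserted {c['inserted']}" if c["inserted"] else "")
            + (f" ({c['note']})" if c["note"] else "")
        )
    for gid, ranked in doc["gc_candidates"].items():
        if ranked:
            top = ranked[0]
            lines.append(
                f"  gap {gid}: top GC match {top['contig']}({top['orientation']}) "
                f"score {top['score']}"
            )
    if doc.get("experiments"):
        ex = doc["experiments"]
        lines.append(
            f"  PCR estimate ({ex['mode']}, n={ex['n']}): "
            f"{ex['estimated_experiments']} (~{ex['one_sig_fig']})"
        )
    t = doc["totals"]
    lines.append(
        f"  totals: {t['gaps_closed']} closed, {t['gaps_open']} open, "
        f"{t['direct_adjacencies']} direct adjacencies"
    )
    return "\n".join(lines) + "\n"
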