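"""Contig adjacency graphs and repeat-aware traversal.

Nodes are contigs annotated with a copy number (*multiplicity*) estimated
from read depth; edges join contig *ends* (B = beginning, E = end of the
forward strand) and arise from reads that span two contig ends.  When the
graph admits exactly one walk that uses every edge once and every contig
exactly its multiplicity times — an Eulerian-style unique traversal — the
genome can be closed in silico by gluing the contigs along the walk.

Orientation algebra used throughout: a contig traversed in ``+``
orientation is entered through its B end and left through its E end; in
``-`` orientation the ends swap roles.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

from .core_io import FormatError, LinkRecord, PafAlignment, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "ContigNode",
    "ContigGraph",
    "Traversal",
    "ConnectingPath",
    "links_from_alignments",
    "build_graph",
    "estimate_multiplicities",
    "find_unique_traversal",
    "reconstruct_sequence",
    "connecting_paths",
]

End = tuple[str, str]  # (contig id, "B"|"E")


def exit_end(orientation: str) -> str:
    """The end a walk leaves a contig through, given its orientation."""
    return "E" if orientation == "+" else "B"


def entry_end(orientation: str) -> str:
    return "B" if orientation == "+" else "E"


def orientation_from_entry(end: str) -> str:
    """Entering a contig through this end implies this orientation."""
    return "+" if end == "B" else "-"


def flip(orientation: str) -> str:
    return "-" if orientation == "+" else "+"


@dataclass
class ContigNode:
    id: str
    length: int
    coverage: float = 0.0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1")
        if self.multiplicity < 1:
            raise ValueError(f"contig {self.id!r}: multiplicity must be >= 1")


@dataclass
class ContigGraph:
    nodes: dict[str, ContigNode]
    edges: list[LinkRecord]
    min_support: int = 2

    def __post_init__(self) -> None:
        self._incidence: dict[End, list[int]] = {}
        for idx, e in enumerate(self.edges):
            for cid, end in ((e.contig_a, e.end_a), (e.contig_b, e.end_b)):
                if cid not in self.nodes:
                    raise FormatError(f"edge references unknown contig {cid!r}")
                self._incidence.setdefault((cid, end), []).append(idx)

    def edges_at(self, end: End) -> list[int]:
        """Indices of edges incident to a contig end."""
        return self._incidence.get(end, [])

    def degree(self, end: End) -> int:
        return len(self.edges_at(end))

    def edge_between(self, end_a: End, end_b: End) -> LinkRecord | None:
        for idx in self.edges_at(end_a):
            e = self.edges[idx]
            if e.other_end(end_a) == end_b:
                return e
        return None


@dataclass
class Traversal:
    """Outcome of the unique-traversal check.

    ``verdict`` is one of ``unique`` (exactly one walk, returned),
    ``multiple`` (the repeat structure admits >= 2 distinct genome
    reconstructions), ``none`` (no complete walk; e.g. a disconnected
    graph), ``inconsistent`` (end degrees contradict the multiplicities),
    or ``undetermined`` (enumeration budget exhausted).
    """

    verdict: str
    walk: list[tuple[str, str]] | None = None  # [(contig id, orientation)]
    topology: str | None = None  # "linear" | "circular"
    junction_offsets: list[int] | None = None  # per junction along the walk


@dataclass
class ConnectingPath:
    """A path of intermediate contigs between two query ends."""

    members: list[tuple[str, str]]  # [(contig id, orientation)], may be empty
    implied_length: int  # intermediate bp implied between the two ends


class ConnectingPathList(list):
    """List of connecting paths; ``truncated`` marks a cut-off enumeration."""

    truncated: bool = False


# ---------------------------------------------------------------------------
# link extraction from read alignments


def _facing_reach(aln: PafAlignment, side: str) -> int:
    """Distance from the alignment to the contig extremity it faces.

    ``side="out"`` is the extremity in the direction the read continues
    after this alignment, ``side="in"`` the one it arrived from.
    """
    toward_end = (side == "out") == (aln.strand == "+")
    if toward_end:
        return aln.contig_len - aln.contig_end
    return aln.contig_start


def links_from_alignments(
    alignments: list[PafAlignment],
    contigs: dict[str, int] | list[SequenceRecord],
    max_end_dist: int = 100,
    min_support: int = 2,
) -> list[LinkRecord]:
    """Derive contig-end links from reads aligned across contig boundaries.

    For each read aligned to two (or, consecutively along the read, more)
    contigs, where each alignment reaches within ``max_end_dist`` of the
    contig extremity facing the other alignment, one link is emitted
    between the two facing ends.  Links are aggregated per end-pair with
    summed support and median offset; pairs below ``min_support`` are
    dropped.
    """
    if not isinstance(contigs, dict):
        contigs = {r.id: len(r.seq) for r in contigs}
    by_read: dict[str, list[PafAlignment]] = {}
    for aln in alignments:
        if aln.contig_id not in contigs:
            raise FormatError(f"alignment references unknown contig {aln.contig_id!r}")
        by_read.setdefault(aln.read_id, []).append(aln)

    raw: dict[tuple[End, End], list[int]] = {}
    for read_id, alns in by_read.items():
        if len(alns) < 2:
            continue
        alns = sorted(alns, key=lambda a: a.read_start)
        for a1, a2 in zip(alns, alns[1:]):
            if a1.contig_id == a2.contig_id:
                continue
            tail1 = _facing_reach(a1, "out")
            head2 = _facing_reach(a2, "in")
            if tail1 > max_end_dist or head2 > max_end_dist:
                logger.debug(
                    "read %s: alignments do not reach facing contig ends", read_id
                )
                continue
            end1 = "E" if a1.strand == "+" else "B"
            end2 = "B" if a2.strand == "+" else "E"
            offset = (a2.read_start - a1.read_end) - tail1 - head2
            link = LinkRecord(a1.contig_id, end1, a2.contig_id, end2, 1, offset)
            raw.setdefault(link.key, []).append(offset)

    out: list[LinkRecord] = []
    for (ea, eb), offsets in sorted(raw.items()):
        support = len(offsets)
        if support < min_support:
            continue
        off = int(statistics.median_low(offsets))
        out.append(LinkRecord(ea[0], ea[1], eb[0], eb[1], support, off))
    return out


# ---------------------------------------------------------------------------
# graph construction


def aggregate_links(links: list[LinkRecord]) -> list[LinkRecord]:
    """Collapse duplicate end-pair links: supports summed, median offset."""
    grouped: dict[tuple[End, End], list[LinkRecord]] = {}
    for lk in links:
        grouped.setdefault(lk.key, []).append(lk)
    out = []
    for (ea, eb), group in sorted(grouped.items()):
        support = sum(lk.support for lk in group)
        offsets = [lk.offset_bp for lk in group for _ in range(lk.support)]
        off = int(statistics.median_low(offsets))
        out.append(LinkRecord(ea[0], ea[1], eb[0], eb[1], support, off))
    return out


def estimate_multiplicities(
    nodes: dict[str, ContigNode],
    coverage: dict[str, float],
    base_length: int = 10_000,
) -> dict[str, ContigNode]:
    """Set node multiplicities from read depth.

    The single-copy baseline is the length-weighted median depth of contigs
    at least ``base_length`` long (long contigs are overwhelmingly unique in
    bacterial assemblies); each contig's multiplicity is
    ``max(1, round(depth / baseline))``.
    """
    for cid, node in nodes.items():
        if cid not in coverage:
            raise FormatError(f"no coverage entry for contig {cid!r}")
        node.coverage = float(coverage[cid])

    longs = [n for n in nodes.values() if n.length >= base_length]
    if not longs:
        logger.warning(
            "no contig >= %d bp for depth baseline; using all contigs", base_length
        )
        longs = list(nodes.values())
    base = _weighted_median([n.coverage for n in longs], [n.length for n in longs])
    if base <= 0:
        raise ValueError("depth baseline is zero; cannot estimate multiplicities")
    for node in nodes.values():
        node.multiplicity = max(1, int(node.coverage / base + 0.5))
    return nodes


def _weighted_median(values: list[float], weights: list[int]) -> float:
    pairs = sorted(zip(values, weights))
    half = sum(weights) / 2.0
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc >= half:
            return v
    return pairs[-1][0]


def build_graph(
    contigs: list[SequenceRecord] | dict[str, int],
    links: list[LinkRecord],
    coverage: dict[str, float],
    min_support: int = 2,
) -> ContigGraph:
    """Aggregate link evidence into a filtered contig adjacency graph."""
    if isinstance(contigs, dict):
        lengths = contigs
    else:
        lengths = {r.id: len(r.seq) for r in contigs}
    nodes = {cid: ContigNode(cid, ln) for cid, ln in lengths.items()}
    estimate_multiplicities(nodes, coverage)
    edges = [e for e in aggregate_links(links) if e.support >= min_support]
    return ContigGraph(nodes=nodes, edges=edges, min_support=min_support)


# ---------------------------------------------------------------------------
# unique traversal


def _degree_profile(graph: ContigGraph) -> tuple[str, list[End]]:
    """Classify end degrees against multiplicities.

    Returns ``("circular", [])`` if every end's degree equals its contig's
    multiplicity, ``("linear", [d1, d2])`` if exactly two ends are deficient
    by one, else ``("inconsistent", deviating_ends)``.
    """
    deficient: list[End] = []
    bad: list[End] = []
    for cid, node in graph.nodes.items():
        for end in ("B", "E"):
            d = graph.degree((cid, end))
            if d == node.multiplicity:
                continue
            if d == node.multiplicity - 1:
                deficient.append((cid, end))
            else:
                bad.append((cid, end))
    if bad:
        return "inconsistent", bad
    if not deficient:
        return "circular", []
    if len(deficient) == 2:
        return "linear", sorted(deficient)
    return "inconsistent", deficient


def _connected(graph: ContigGraph) -> bool:
    """Whether all contigs lie in one component (edges join contigs)."""
    ids = list(graph.nodes)
    if len(ids) <= 1:
        return True
    adj: dict[str, set[str]] = {cid: set() for cid in ids}
    for e in graph.edges:
        adj[e.contig_a].add(e.contig_b)
        adj[e.contig_b].add(e.contig_a)
    seen = {ids[0]}
    stack = [ids[0]]
    while stack:
        for nxt in adj[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return len(seen) == len(ids)


def _rc_walk(walk: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(cid, flip(o)) for cid, o in reversed(walk)]


def canonical_walk(walk: list[tuple[str, str]], topology: str) -> tuple:
    """Canonical form of a walk up to rotation (circular) and reverse
    complement, used to decide whether two walks describe the same
    molecule."""
    if topology == "linear":
        return min(tuple(walk), tuple(_rc_walk(walk)))
    best = None
    for w in (walk, _rc_walk(walk)):
        n = len(w)
        for r in range(n):
            cand = tuple(w[r:] + w[:r])
            if best is None or cand < best:
                best = cand
    return best


class _Budget:
    __slots__ = ("left",)

    def __init__(self, n: int) -> None:
        self.left = n

    def spend(self) -> bool:
        self.left -= 1
        return self.left >= 0


def _enumerate_walks(
    graph: ContigGraph,
    start: tuple[str, str],
    topology: str,
    budget: _Budget,
    stop_after: int | None,
) -> tuple[set[tuple], bool]:
    """Backtracking enumeration of complete walks from a fixed start.

    Returns (set of canonical walks, budget_exhausted).  When
    ``stop_after`` is given, stops as soon as that many *distinct* walks
    have been seen.
    """
    remaining_mult = {cid: n.multiplicity for cid, n in graph.nodes.items()}
    n_edges = len(graph.edges)
    used = [False] * n_edges
    found: set[tuple] = set()
    exhausted = False

    start_cid, start_orient = start
    walk: list[tuple[str, str]] = [(start_cid, start_orient)]
    offsets: list[int] = []
    remaining_mult[start_cid] -= 1
    walks_with_offsets: dict[tuple, tuple[list, list]] = {}

    def rec(cur_exit: End, edges_left: int) -> bool:
        nonlocal exhausted
        if edges_left == 0 and all(v == 0 for v in remaining_mult.values()):
            if topology == "linear":
                key = canonical_walk(walk, topology)
                if key not in found:
                    found.add(key)
                    walks_with_offsets[key] = (list(walk), list(offsets))
                return stop_after is not None and len(found) >= stop_after
            # circular walks are closed by the final edge below, not here
        for idx in graph.edges_at(cur_exit):
            if used[idx]:
                continue
            if not budget.spend():
                exhausted = True
                return True
            e = graph.edges[idx]
            nxt_cid, nxt_end = e.other_end(cur_exit)
            if topology == "circular" and edges_left == 1:
                # the last edge must close the circuit back into the start
                if (nxt_cid, nxt_end) == (start_cid, entry_end(start_orient)) and all(
                    v == 0 for v in remaining_mult.values()
                ):
                    key = canonical_walk(walk, topology)
                    if key not in found:
                        found.add(key)
                        walks_with_offsets[key] = (list(walk), offsets + [e.offset_bp])
                    if stop_after is not None and len(found) >= stop_after:
                        return True
                continue
            if remaining_mult.get(nxt_cid, 0) < 1:
                continue
            orient = orientation_from_entry(nxt_end)
            used[idx] = True
            remaining_mult[nxt_cid] -= 1
            walk.append((nxt_cid, orient))
            offsets.append(e.offset_bp)
            if rec((nxt_cid, exit_end(orient)), edges_left - 1):
                return True
            offsets.pop()
            walk.pop()
            remaining_mult[nxt_cid] += 1
            used[idx] = False
        return False

    rec((start_cid, exit_end(start_orient)), n_edges)
    _enumerate_walks.last_walks = walks_with_offsets  # type: ignore[attr-defined]
    return found, exhausted


def find_unique_traversal(graph: ContigGraph, max_steps: int = 1_000_000) -> Traversal:
    """Decide whether the graph admits a unique genome reconstruction.

    Checks end-degree balance against multiplicities and connectivity, then
    enumerates edge-distinct walks by backtracking, stopping at the second
    walk that is distinct up to rotation (circular) and reverse complement.
    """
    if not graph.nodes:
        return Traversal(verdict="none")
    if not graph.edges:
        if len(graph.nodes) == 1:
            (cid,) = graph.nodes
            if graph.nodes[cid].multiplicity == 1:
                return Traversal(
                    verdict="unique",
                    walk=[(cid, "+")],
                    topology="linear",
                    junction_offsets=[],
                )
        return Traversal(verdict="none")
    if not _connected(graph):
        return Traversal(verdict="none")

    topology, special = _degree_profile(graph)
    if topology == "inconsistent":
        return Traversal(verdict="inconsistent")

    if topology == "circular":
        start_cid = min(graph.nodes)
        start = (start_cid, "+")
    else:
        d_cid, d_end = special[0]
        # the walk's first contig is entered through nothing; its free end
        # is the deficient one
        start = (d_cid, orientation_from_entry(d_end))

    budget = _Budget(max_steps)
    found, exhausted = _enumerate_walks(graph, start, topology, budget, stop_after=2)
    if len(found) >= 2:
        return Traversal(verdict="multiple", topology=topology)
    if exhausted:
        return Traversal(verdict="undetermined", topology=topology)
    if not found:
        return Traversal(verdict="none", topology=topology)
    key = next(iter(found))
    walk, offsets = _enumerate_walks.last_walks[key]  # type: ignore[attr-defined]
    return Traversal(
        verdict="unique", walk=walk, topology=topology, junction_offsets=offsets
    )


# ---------------------------------------------------------------------------
# sequence reconstruction


def _identity(a: str, b: str) -> float:
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reconstruct_sequence(
    traversal: Traversal,
    contigs: list[SequenceRecord] | dict[str, str],
    min_identity: float = 0.95,
    out_id: str = "reconstruction",
) -> SequenceRecord:
    """Glue contigs along a unique walk into one genome sequence.

    Negative junction offsets are merged after verifying >= ``min_identity``
    over the overlap (the earlier contig's copy is kept); positive offsets
    are filled with Ns.  Circular reconstructions are rotated to start at
    the lexicographically smallest contig id in forward orientation.
    """
    if traversal.verdict != "unique" or traversal.walk is None:
        raise ValueError("reconstruction requires a unique traversal")
    seqs = contigs if isinstance(contigs, dict) else {r.id: r.seq for r in contigs}

    walk = list(traversal.walk)
    offsets = list(traversal.junction_offsets or [])
    circular = traversal.topology == "circular"
    if circular:
        # rotate so the walk starts at the smallest contig id in + orientation
        candidates = [i for i, (cid, o) in enumerate(walk) if o == "+"]
        if not candidates:
            walk = _rc_walk(walk)
            offsets = list(reversed(offsets))
            candidates = [i for i, (cid, o) in enumerate(walk) if o == "+"]
        r = min(candidates, key=lambda i: walk[i][0])
        walk = walk[r:] + walk[:r]
        offsets = offsets[r:] + offsets[:r]

    def oriented(cid: str, o: str) -> str:
        s = seqs[cid]
        return s if o == "+" else revcomp(s)

    pieces = [oriented(*walk[0])]
    n_junctions = len(walk) - 1 + (1 if circular else 0)
    for j in range(len(walk) - 1):
        off = offsets[j] if j < len(offsets) else 0
        nxt = oriented(*walk[j + 1])
        if off < 0:
            ov = -off
            prev_tail = pieces[-1][-ov:]
            ident = _identity(prev_tail, nxt[:ov])
            if ident < min_identity:
                raise ValueError(
                    f"junction {walk[j][0]}->{walk[j + 1][0]}: overlap identity "
                    f"{ident:.2f} below {min_identity:.2f} over {ov} bp"
                )
            pieces.append(nxt[ov:])
        else:
            pieces.append("N" * off + nxt)
    seq = "".join(pieces)
    if circular and n_junctions == len(offsets):
        off = offsets[-1]
        if off < 0:
            ov = -off
            ident = _identity(seq[-ov:], seq[:ov])
            if ident < min_identity:
                raise ValueError(
                    f"closing junction {walk[-1][0]}->{walk[0][0]}: overlap "
                    f"identity {ident:.2f} below {min_identity:.2f}"
                )
            seq = seq[:-ov]
        elif off > 0:
            seq = seq + "N" * off
    desc = f"{traversal.topology} reconstruction of {len(walk)} contig copies"
    return SequenceRecord(out_id, seq, desc)


# ---------------------------------------------------------------------------
# connecting paths


def connecting_paths(
    graph: ContigGraph,
    end_a: End,
    end_b: End,
    max_path_bp: int,
    max_paths: int = 100,
) -> ConnectingPathList:
    """Enumerate paths of intermediate contigs joining two contig ends.

    Each intermediate contig may be used at most its multiplicity times;
    paths whose implied intermediate length exceeds ``max_path_bp`` are
    pruned.  Results are sorted by implied length; the list's ``truncated``
    attribute is set when enumeration stopped at ``max_paths``.
    """
    for end in (end_a, end_b):
        if end[0] not in graph.nodes:
            raise FormatError(f"unknown contig end {end}")
    out = ConnectingPathList()
    remaining = {cid: n.multiplicity for cid, n in graph.nodes.items()}
    used = [False] * len(graph.edges)
    members: list[tuple[str, str]] = []

    def rec(cur: End, length: int) -> bool:
        """Returns True when enumeration must stop (max_paths reached)."""
        for idx in graph.edges_at(cur):
            if used[idx]:
                continue
            e = graph.edges[idx]
            nxt_cid, nxt_end = e.other_end(cur)
            new_len = length + e.offset_bp
            if (nxt_cid, nxt_end) == end_b:
                if new_len <= max_path_bp:
                    out.append(ConnectingPath(list(members), max(0, new_len)))
                    if len(out) >= max_paths:
                        out.truncated = True
                        return True
                continue
            if remaining.get(nxt_cid, 0) < 1:
                continue
            orient = orientation_from_entry(nxt_end)
            step_len = new_len + graph.nodes[nxt_cid].length
            if step_len > max_path_bp:
                continue
            used[idx] = True
            remaining[nxt_cid] -= 1
            members.append((nxt_cid, orient))
            stop = rec((nxt_cid, exit_end(orient)), step_len)
            members.pop()
            remaining[nxt_cid] += 1
            used[idx] = False
            if stop:
                return True
        return False

    rec(end_a, 0)
    out.sort(key=lambda p: (p.implied_length, tuple(p.members)))
    return out
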