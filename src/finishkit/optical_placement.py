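"""In-silico digestion and placement of contigs on ordered restriction maps.

A contig is digested in silico with the map's enzyme and its internal
restriction fragments are aligned against windows of the genome-wide map by
dynamic programming.  The alignment matches cut sites monotonically,
merging up to ``delta`` consecutive fragments on either side per matched
block to absorb missed cuts (a real cut invisible in the map) and false
cuts (a spurious map cut).  A matched block pairing expected (sequence)
length ``e`` with observed (map) length ``o`` costs
``(o - e)^2 / (s*e + (cv*e)^2)`` — a chi-square-style sizing term whose
variance combines a Poisson-like floor with the relative sizing error of
the mapping process — plus ``c_miss`` per unmatched contig cut and
``c_false`` per unmatched map cut (discounted to ``c_floor`` when the cut
sits next to a near-detection-floor fragment, whose visibility is an
instrument artefact rather than evidence).  A placement additionally pays
a global span-consistency term, and counts as *unique* only when every
rival location scores at least ``margin`` worse.

Optical maps cannot resolve very small fragments, so both the simulated
maps and the contig digests are *conditioned* before alignment: fragments
below the detection floor ``min_frag`` are merged into a neighbour.  This
keeps the two fragment patterns statistically comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .core_io import RestrictionMap, Scaffold, ScaffoldPart, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "InSilicoDigest",
    "PlacementParams",
    "Placement",
    "digest",
    "merge_small_fragments",
    "condition_digest",
    "align_digest_to_window",
    "place_contig",
    "place_all",
    "build_map_scaffold",
]

INF = float("inf")


@dataclass
class InSilicoDigest:
    """Restriction-site layout of one sequence.

    ``cut_positions`` are 0-based start indices of recognition-site
    occurrences on the forward strand.  For a linear molecule,
    ``left_end``/``right_end`` are the terminal partial fragments (bp from
    the molecule ends to the first/last cut) and ``internal_fragments`` the
    cut-to-cut distances; for a circular molecule all fragments are
    internal (wrapping across the origin) and the terminal ends are 0.
    """

    contig_id: str
    enzyme: str
    site: str
    topology: str
    length: int
    cut_positions: list[int]
    internal_fragments: list[int]
    left_end: int
    right_end: int

    @property
    def fragments(self) -> list[int]:
        """Full fragment list including terminal partials (linear)."""
        if self.topology == "circular":
            return list(self.internal_fragments)
        out = [self.left_end] + list(self.internal_fragments) + [self.right_end]
        return [f for f in out if f > 0] or [self.length]


def _find_sites(seq: str, site: str) -> list[int]:
    out, start = [], 0
    while True:
        i = seq.find(site, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1  # allow overlapping occurrences


def digest(
    seq: str | SequenceRecord,
    site: str,
    topology: str = "linear",
    contig_id: str = "",
    enzyme: str = "",
) -> InSilicoDigest:
    """Cut a sequence at every occurrence of a recognition site.

    The cut coordinate is the start index of the site; optical maps record
    site positions, and actual cleavage offsets are far below map
    resolution.  For circular molecules, site occurrences spanning the
    origin are found by scanning a short wrap-around extension.
    """
    if isinstance(seq, SequenceRecord):
        contig_id = contig_id or seq.id
        seq = seq.seq
    if len(site) < 4:
        raise ValueError("recognition site must be at least 4 bp")
    if set(site) - set("ACGT"):
        raise ValueError(f"degenerate or invalid site {site!r}")
    L = len(seq)
    cuts = _find_sites(seq, site)
    if topology == "circular":
        wrap = seq[L - len(site) + 1:] + seq[: len(site) - 1]
        for i in _find_sites(wrap, site):
            cuts.append((L - len(site) + 1 + i) % L)
        cuts = sorted(set(cuts))
        if not cuts:
            internal = [L]
        else:
            internal = [b - a for a, b in zip(cuts, cuts[1:])]
            internal.append(L - cuts[-1] + cuts[0])
        return InSilicoDigest(contig_id, enzyme, site, topology, L, cuts, internal, 0, 0)
    if not cuts:
        return InSilicoDigest(contig_id, enzyme, site, topology, L, [], [], L, 0)
    internal = [b - a for a, b in zip(cuts, cuts[1:])]
    return InSilicoDigest(
        contig_id, enzyme, site, topology, L, cuts, internal, cuts[0], L - cuts[-1]
    )


def merge_small_fragments(
    fragments: list[int], floor: int, circular: bool = False
) -> list[int]:
    """Merge fragments below a detection floor into their smaller neighbour.

    Models the failure of optical mapping to resolve small restriction
    fragments; merging (rather than deleting) conserves total length.
    """
    frags = list(fragments)
    while len(frags) > 1:
        small = [
            (f, i) for i, f in enumerate(frags) if f < floor
        ]
        if not small:
            break
        _, i = min(small)
        n = len(frags)
        if circular:
            left, right = (i - 1) % n, (i + 1) % n
        else:
            left = i - 1 if i > 0 else None
            right = i + 1 if i < n - 1 else None
        if left is None:
            tgt = right
        elif right is None:
            tgt = left
        else:
            tgt = left if frags[left] <= frags[right] else right
        frags[tgt] += frags[i]
        del frags[i]
    return frags


def condition_digest(
    dg: InSilicoDigest, floor: int
) -> tuple[list[int], int, int]:
    """Apply the detection floor to a linear contig digest.

    Internal fragments below ``floor`` are merged into their smaller
    neighbour; a sub-floor fragment at the boundary is absorbed into the
    terminal end (dropping that cut, as the mapping platform would).
    Returns (conditioned internal fragments, left_end, right_end).
    """
    items: list[list] = [["L", dg.left_end]]
    items += [["I", f] for f in dg.internal_fragments]
    items.append(["R", dg.right_end])
    while True:
        small = [
            (val, i)
            for i, (kind, val) in enumerate(items)
            if kind == "I" and val < floor
        ]
        if not small:
            break
        _, i = min(small)
        lv, rv = items[i - 1][1], items[i + 1][1]
        tgt = i - 1 if lv <= rv else i + 1
        items[tgt][1] += items[i][1]
        del items[i]
    internal = [val for kind, val in items if kind == "I"]
    return internal, items[0][1], items[-1][1]


@dataclass
class PlacementParams:
    """Tunable scoring constants for map placement.

    ``s`` scales the sizing variance (bp); ``c_miss``/``c_false`` penalize
    unmatched contig/map cuts; ``delta`` bounds how many consecutive
    fragments may merge per matched block; ``t_max`` is the acceptance
    ceiling on the best placement's mean score per contig fragment;
    ``overlap_collapse`` is the map-interval overlap fraction above which
    two placements are treated as the same location; ``min_frag`` is the
    detection floor applied to contig digests before alignment; ``margin``
    is the score separation a best placement needs over every rival
    location to count as unique (rivals within the margin make it
    ambiguous, rivals beyond it are discarded as noise).
    """

    s: float = 30.0
    sizing_cv: float = 0.05
    c_miss: float = 1.5
    c_false: float = 3.0
    c_floor: float = 0.5
    delta: int = 4
    t_max: float = 2.0
    overlap_collapse: float = 0.5
    min_frag: int = 2000
    margin: float = 0.8

    def __post_init__(self) -> None:
        if min(self.s, self.c_miss, self.c_false, self.t_max) <= 0:
            raise ValueError("scoring constants must be positive")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")


@dataclass
class Placement:
    """One contig located on one map."""

    contig_id: str
    map_id: str
    start: int
    end: int
    orientation: str
    score: float
    mean_score: float = INF
    matched: list[tuple[int, int]] = field(default_factory=list)
    status: str = "unplaced"
    reason: str | None = None
    contig_length: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start


def align_digest_to_window(
    contig_fragments: list[int],
    map_fragments_window: list[int],
    params: PlacementParams | None = None,
) -> tuple[float, list[tuple[int, int]]]:
    """Optimal monotone cut-to-cut matching of two fragment lists.

    Both lists must be fully consumed; each matched block merges at most
    ``delta`` consecutive fragments on either side.  Returns the minimal
    total score and the matched (contig cut, map cut) boundary pairs,
    including the anchoring pair (0, 0) and the final pair (n, m); the
    score is infinite when no matching exists under the merge bound.
    """
    p = params or PlacementParams()
    f, g = list(contig_fragments), list(map_fragments_window)
    n, m = len(f), len(g)
    if n < 2:
        raise ValueError("contig must have at least 2 internal fragments")
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    D[0][0] = 0.0
    pf = [0] * (n + 1)
    for i in range(n):
        pf[i + 1] = pf[i] + f[i]
    pg = [0] * (m + 1)
    for j in range(m):
        pg[j + 1] = pg[j] + g[j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best, barg = INF, None
            for a in range(1, min(p.delta, i) + 1):
                e = pf[i] - pf[i - a]
                base_a = (a - 1) * p.c_miss
                for b in range(1, min(p.delta, j) + 1):
                    prev = D[i - a][j - b]
                    if prev == INF:
                        continue
                    o = pg[j] - pg[j - b]
                    var = p.s * e + (p.sizing_cv * e) ** 2
                    cost = prev + (o - e) ** 2 / var + base_a + (b - 1) * p.c_false
                    if cost < best:
                        best, barg = cost, (i - a, j - b)
            if barg is not None:
                D[i][j] = best
                parent[(i, j)] = barg
    if D[n][m] == INF:
        return INF, []
    pairs = [(n, m)]
    cur = (n, m)
    while cur != (0, 0):
        cur = parent[cur]
        pairs.append(cur)
    return D[n][m], pairs[::-1]


def _window_dp(
    f: list[int],
    G: list[int],
    j0: int,
    lead_ok: list[bool],
    p: PlacementParams,
    max_span: float,
    cap: float,
) -> list[tuple[int, int, float, dict]]:
    """DP anchored at map cut ``j0``: align contig fragments ``f`` (after an
    allowed lead skip) against map fragments ``G[j0:]``.

    Returns candidate endpoints ``(i, j, score, parents)`` for every state
    with all-but-a-trailing-skip of the contig consumed.
    """
    n = len(f)
    delta = p.delta
    maxJ = len(G) - j0
    D = [[INF] * (maxJ + 1) for _ in range(n + 1)]
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    for a0 in range(min(delta, n - 2) + 1):
        if a0 < len(lead_ok) and lead_ok[a0]:
            D[a0][0] = a0 * p.c_miss
    pf = [0] * (n + 1)
    for i in range(n):
        pf[i + 1] = pf[i] + f[i]
    # cut-skip penalties: a cut flanked by a near-floor fragment may simply
    # have crossed the detection threshold on the other side (a deterministic
    # instrument effect), so skipping it is cheap; prefix sums let a block
    # sum its skipped-cut penalties in O(1)
    borderline = 1.2 * p.min_frag if p.min_frag else 0.0
    pen_f = [0.0] * (n + 1)  # pen_f[k]: cumulative penalty of contig cuts 1..k-1
    for k in range(1, n):
        c = p.c_floor if min(f[k - 1], f[k]) <= borderline else p.c_miss
        pen_f[k + 1] = pen_f[k] + c
    pen_g = [0.0] * (maxJ + 1)
    for t in range(1, maxJ):
        c = p.c_floor if min(G[j0 + t - 1], G[j0 + t]) <= borderline else p.c_false
        pen_g[t + 1] = pen_g[t] + c
    results: list[tuple[int, int, float, dict]] = []
    span = 0.0
    for j in range(1, maxJ + 1):
        span += G[j0 + j - 1]
        if span > max_span:
            break
        col_has = False
        for i in range(1, n + 1):
            best, barg = INF, None
            for a in range(1, min(delta, i) + 1):
                e = pf[i] - pf[i - a]
                if e == 0:
                    continue
                base_a = pen_f[i] - pen_f[i - a + 1]
                var = p.s * e + (p.sizing_cv * e) ** 2
                og = 0
                for b in range(1, min(delta, j) + 1):
                    og += G[j0 + j - b]
                    prev = D[i - a][j - b]
                    if prev == INF:
                        continue
                    cost = (
                        prev + (og - e) ** 2 / var + base_a
                        + (pen_g[j] - pen_g[j - b + 1])
                    )
                    if cost < best:
                        best, barg = cost, (i - a, j - b)
            if barg is not None and best <= cap:
                D[i][j] = best
                parent[(i, j)] = barg
                col_has = True
                if i >= n - (delta - 1) and i >= 2:
                    results.append((i, j, best, parent))
        # abandon this anchor once the last `delta` columns are all dead
        # (column 0 still seeds columns 1..delta, so never break before that)
        if not col_has and j >= delta and all(
            D[i][jj] == INF
            for jj in range(j - delta + 1, j + 1)
            for i in range(n + 1)
        ):
            break
    return results


def place_contig(
    dg: InSilicoDigest,
    rmap: RestrictionMap,
    params: PlacementParams | None = None,
) -> list[Placement]:
    """Scan a contig digest against every window of a restriction map.

    Both orientations are tried; circular maps are linearized by doubling
    the fragment list, keeping placements that start in the first copy.
    Placements with mean score per contig fragment above ``t_max`` are
    rejected; surviving placements overlapping by more than
    ``overlap_collapse`` of the shorter interval are collapsed to the best
    one.  Status is ``unique`` for exactly one survivor, ``ambiguous`` for
    several, ``unplaced`` for none.  Contigs whose conditioned digest has
    fewer than 2 internal fragments are never placed.
    """
    p = params or PlacementParams()
    if dg.enzyme and rmap.enzyme and dg.enzyme != rmap.enzyme:
        raise ValueError(
            f"digest enzyme {dg.enzyme!r} does not match map enzyme {rmap.enzyme!r}"
        )
    internal, left_end, right_end = condition_digest(dg, p.min_frag)
    n = len(internal)
    if n < 2:
        return [
            Placement(
                dg.contig_id, rmap.map_id, 0, 0, "+", INF,
                status="unplaced", reason="too few sites",
                contig_length=dg.length,
            )
        ]

    L = rmap.length
    circular = rmap.topology == "circular"
    frags = rmap.fragments
    m = len(frags)
    if circular:
        G = frags + frags
        cutpos = [0] * (2 * m + 1)
        for k in range(2 * m):
            cutpos[k + 1] = cutpos[k] + G[k]
        starts = range(0, m)
    else:
        G = list(frags)
        cutpos = [0] * (m + 1)
        for k in range(m):
            cutpos[k + 1] = cutpos[k] + G[k]
        starts = range(1, m)

    tot = sum(internal)
    max_span = tot * 1.3 + 6.0 * math.sqrt(p.s * max(tot, 1)) + 2 * p.min_frag
    cap = p.t_max * n + 1e-9

    candidates: list[Placement] = []
    for orientation in ("+", "-"):
        if orientation == "+":
            f, l_end, r_end = internal, left_end, right_end
        else:
            f, l_end, r_end = internal[::-1], right_end, left_end
        lead_sums = [0] * p.delta
        for a0 in range(1, p.delta):
            lead_sums[a0] = lead_sums[a0 - 1] + (f[a0 - 1] if a0 - 1 < n else 0)
        for j0 in starts:
            if circular:
                def back_frag(t, _j0=j0):
                    return frags[(_j0 - 1 - t) % m]
            else:
                def back_frag(t, _j0=j0):
                    idx = _j0 - 1 - t
                    return G[idx] if idx >= 0 else None
            lead_ok, lead_pen = [], []
            for a0 in range(p.delta):
                le = l_end + lead_sums[a0]
                ok, pen = _terminal_fit(le, back_frag, p)
                lead_ok.append(ok)
                lead_pen.append(pen)
            if not any(lead_ok):
                continue
            best_here: Placement | None = None
            for i_end, j, score, parent in _window_dp(f, G, j0, lead_ok, p, max_span, cap):
                a1 = n - i_end
                j1 = j0 + j
                if circular:
                    def fwd_frag(t, _j1=j1):
                        return frags[(_j1 + t) % m]
                else:
                    if j1 >= m:
                        continue
                    def fwd_frag(t, _j1=j1):
                        idx = _j1 + t
                        return G[idx] if idx < m else None
                r_eff = r_end + sum(f[i_end:])
                r_ok, r_pen = _terminal_fit(r_eff, fwd_frag, p)
                if not r_ok:
                    continue
                # trace back to find the lead skip actually used
                pairs = [(i_end, j)]
                cur = (i_end, j)
                while cur[1] != 0:
                    cur = parent[cur]
                    pairs.append(cur)
                a0 = cur[0]
                # global span consistency: sizing errors accumulate over the
                # matched region, so the total observed span must agree with
                # the expected span within the summed per-fragment variance;
                # spurious windows tend to compress or stretch globally
                span_exp = sum(f[a0:i_end])
                span_obs = cutpos[j1] - cutpos[j0]
                var_span = p.s * max(span_exp, 1) + p.sizing_cv**2 * sum(
                    fk * fk for fk in f[a0:i_end]
                )
                total = (
                    score + a1 * p.c_miss + lead_pen[a0] + r_pen
                    + (span_obs - span_exp) ** 2 / var_span
                )
                mean = total / n
                l_eff = l_end + lead_sums[a0] if a0 < p.delta else l_end
                start = cutpos[j0] - l_eff
                end = cutpos[j1] + r_eff
                if circular:
                    if start < 0:
                        start += L
                        end += L
                pl = Placement(
                    dg.contig_id, rmap.map_id, int(start), int(end), orientation,
                    total, mean,
                    matched=[(ci, j0 + mj) for ci, mj in pairs[::-1]],
                    status="candidate", contig_length=dg.length,
                )
                if best_here is None or pl.score < best_here.score:
                    best_here = pl
            if best_here is not None:
                candidates.append(best_here)

    if not candidates:
        return [
            Placement(
                dg.contig_id, rmap.map_id, 0, 0, "+", INF,
                status="unplaced", reason="no acceptable alignment",
                contig_length=dg.length,
            )
        ]

    kept: list[Placement] = []
    for pl in sorted(candidates, key=lambda x: x.score):
        absorbed = False
        for other in kept:
            # only same-orientation overlaps are the same placement; an
            # opposite-strand overlap is a genuine rival interpretation
            if pl.orientation == other.orientation and _overlap_frac(
                pl, other, L if circular else None
            ) > p.overlap_collapse:
                absorbed = True
                break
        if not absorbed:
            kept.append(pl)
    best = kept[0]
    if best.mean_score > p.t_max:
        return [
            Placement(
                dg.contig_id, rmap.map_id, 0, 0, "+", best.score,
                status="unplaced", reason="best score above threshold",
                contig_length=dg.length,
            )
        ]
    # uniqueness by score separation: rival locations within `margin` of the
    # best make the placement ambiguous, worse ones are discarded
    kept = [pl for pl in kept if pl.score <= best.score + p.margin]
    status = "unique" if len(kept) == 1 else "ambiguous"
    for pl in kept:
        pl.status = status
    return kept


def _end_slack(end_len: float, p: PlacementParams) -> float:
    """Allowed overhang of a terminal partial fragment beyond its spanning
    map region: sizing drift plus one undetected sub-floor fragment."""
    return 0.1 * end_len + p.min_frag + 500


def _terminal_fit(
    end_len: float,
    frag_at: "callable",
    p: PlacementParams,
) -> tuple[bool, float]:
    """Can a terminal partial fragment of ``end_len`` bp fit into the map
    region beyond a boundary cut?

    ``frag_at(t)`` returns the t-th map fragment walking away from the
    boundary (None past a linear map end).  The terminal region normally
    lies inside one map fragment, but a false cut (or, on a circular map,
    the arbitrary origin cut) may subdivide it; each swallowed map cut is
    charged ``c_false``.  Returns (fits, penalty).
    """
    slack = _end_slack(end_len, p)
    acc = 0.0
    for t in range(p.delta):
        frag = frag_at(t)
        if frag is None:
            # ran off a linear map end: the rest must fit in the slack
            return (end_len - acc <= slack, t * p.c_false)
        acc += frag
        if acc + slack >= end_len:
            return (True, t * p.c_false)
    return (False, 0.0)


def _overlap_frac(a: Placement, b: Placement, L: int | None) -> float:
    shorter = min(a.span, b.span)
    if shorter <= 0:
        return 0.0
    best = 0
    shifts = (0,) if L is None else (-L, 0, L)
    for sh in shifts:
        lo = max(a.start + sh, b.start)
        hi = min(a.end + sh, b.end)
        best = max(best, hi - lo)
    return best / shorter


def place_all(
    contigs: list[SequenceRecord],
    rmap: RestrictionMap,
    params: PlacementParams | None = None,
) -> list[Placement]:
    """Digest and place every contig on one map."""
    out: list[Placement] = []
    for rec in contigs:
        dg = digest(rec, rmap.site, "linear", enzyme=rmap.enzyme)
        out.extend(place_contig(dg, rmap, params))
    return out


def build_map_scaffold(
    placements: list[Placement],
    rmap: RestrictionMap,
    scaffold_id: str | None = None,
) -> Scaffold:
    """Order uniquely placed contigs along one map into a scaffold.

    Placements overlapping beyond ``max(5 kbp, 20% of the shorter)`` are
    resolved by dropping the worse-scoring one (logged as a conflict).
    Gaps are map distances between consecutive placements and may be
    slightly negative (within the overlap tolerance); they are clamped to
    0 only on AGP output.
    """
    sid = scaffold_id or f"scaffold_{rmap.map_id}"
    uniq = sorted(
        (p for p in placements if p.status == "unique"), key=lambda p: p.start
    )
    conflicts: list[str] = []
    kept: list[Placement] = []
    for pl in uniq:
        if kept:
            prev = kept[-1]
            overlap = prev.end - pl.start
            tol = max(5000, 0.2 * min(prev.span, pl.span))
            if overlap > tol:
                worse = pl if pl.score >= prev.score else prev
                better = prev if worse is pl else pl
                conflicts.append(
                    f"{worse.contig_id} overlaps {better.contig_id} by {overlap} bp; "
                    f"dropped {worse.contig_id} (worse score)"
                )
                if worse is prev:
                    kept[-1] = pl
                continue
        kept.append(pl)
    parts = [
        ScaffoldPart(
            p.contig_id, p.contig_length or p.span, p.orientation,
            p.start, p.end, p.score,
        )
        for p in kept
    ]
    gaps = [int(b.start - a.end) for a, b in zip(kept, kept[1:])]
    L = rmap.length
    covered = 0
    prev_end = None
    for p in kept:
        s, e = max(0, p.start), min(L, p.end)
        if prev_end is not None and s < prev_end:
            s = prev_end
        if e > s:
            covered += e - s
            prev_end = e
        elif prev_end is None or e > prev_end:
            prev_end = e
    coverage = covered / L if L else 0.0
    return Scaffold(
        id=sid, parts=parts, gaps=gaps, map_id=rmap.map_id,
        map_length=L, coverage_frac=coverage, conflicts=conflicts,
    )
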