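"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration, sharing no
logic with the library implementations they check.
"""

from __future__ import annotations

from itertools import product


# ---------------------------------------------------------------------------
# Eulerian-style walk enumeration on a contig-end graph


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def _rc(walk: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(c, _flip(o)) for c, o in reversed(walk)]


def canon(walk: list[tuple[str, str]], circular: bool) -> tuple:
    if not circular:
        return min(tuple(walk), tuple(_rc(walk)))
    best = None
    for w in (walk, _rc(walk)):
        for r in range(len(w)):
            cand = tuple(w[r:] + w[:r])
            if best is None or cand < best:
                best = cand
    return best


def enumerate_all_walks(nodes: dict[str, int], edges: list[tuple]) -> dict:
    """Exhaustively enumerate complete walks of a contig-end graph.

    ``nodes``: contig id -> multiplicity.  ``edges``: list of
    ((contig_a, end_a), (contig_b, end_b)) tuples, each usable once.
    Returns a dict with the degree classification and the sets of distinct
    circular and linear walks (canonical forms).
    """
    deg: dict[tuple[str, str], int] = {}
    for (a, ea), (b, eb) in edges:
        deg[(a, ea)] = deg.get((a, ea), 0) + 1
        deg[(b, eb)] = deg.get((b, eb), 0) + 1

    deficient, bad = [], []
    for c, mult in nodes.items():
        for e in ("B", "E"):
            d = deg.get((c, e), 0)
            if d == mult:
                continue
            (deficient if d == mult - 1 else bad).append((c, e))
    if bad:
        shape = "inconsistent"
    elif not deficient:
        shape = "circular"
    elif len(deficient) == 2:
        shape = "linear"
    else:
        shape = "inconsistent"

    walks: dict[str, set] = {"circular": set(), "linear": set()}

    def other(edge, end):
        return edge[1] if edge[0] == end else edge[0]

    def extend(walk, used, remaining, cur_exit, circular, close_at):
        if not any(u is False for u in used) and all(v == 0 for v in remaining.values()):
            if not circular:
                walks["linear"].add(canon(walk, False))
            return
        for idx, edge in enumerate(edges):
            if used[idx]:
                continue
            if cur_exit not in (edge[0], edge[1]):
                continue
            # a self-loop edge may be traversed from either endpoint
            nxts = [other(edge, cur_exit)]
            for nxt in nxts:
                c2, e2 = nxt
                if circular and sum(used) == len(edges) - 1:
                    if nxt == close_at and all(v == 0 for v in remaining.values()):
                        walks["circular"].add(canon(walk, True))
                    continue
                if remaining.get(c2, 0) < 1:
                    continue
                o2 = "+" if e2 == "B" else "-"
                used[idx] = True
                remaining[c2] -= 1
                walk.append((c2, o2))
                nxt_exit = (c2, "E" if o2 == "+" else "B")
                extend(walk, used, remaining, nxt_exit, circular, close_at)
                walk.pop()
                remaining[c2] += 1
                used[idx] = False

    if shape == "circular" and edges:
        start = min(nodes)
        remaining = dict(nodes)
        remaining[start] -= 1
        extend([(start, "+")], [False] * len(edges), remaining,
               (start, "E"), True, (start, "B"))
    elif shape == "linear":
        for (c, e) in deficient:
            o = "+" if e == "B" else "-"
            remaining = dict(nodes)
            remaining[c] -= 1
            extend([(c, o)], [False] * len(edges), remaining,
                   (c, "E" if o == "+" else "B"), False, None)

    return {"shape": shape, "circular": walks["circular"], "linear": walks["linear"]}


def oracle_verdict(nodes: dict[str, int], edges: list[tuple]) -> tuple[str, set]:
    """Expected traversal verdict and the set of distinct walks."""
    res = enumerate_all_walks(nodes, edges)
    if res["shape"] == "inconsistent":
        return "inconsistent", set()
    found = res[res["shape"]]
    if not found:
        return "none", set()
    if len(found) == 1:
        return "unique", found
    return "multiple", found


# ---------------------------------------------------------------------------
# restriction-fragment alignment by exhaustive block enumeration


def brute_force_align(
    f: list[int], g: list[int],
    s: float, cv: float, c_miss: float, c_false: float, delta: int,
) -> float:
    """Minimal cost over all monotone block matchings consuming both lists."""
    best = [float("inf")]

    def rec(i, j, acc):
        if acc >= best[0]:
            return
        if i == len(f) and j == len(g):
            best[0] = acc
            return
        for a in range(1, delta + 1):
            if i + a > len(f):
                break
            e = sum(f[i:i + a])
            var = s * e + (cv * e) ** 2
            for b in range(1, delta + 1):
                if j + b > len(g):
                    break
                o = sum(g[j:j + b])
                cost = (o - e) ** 2 / var + (a - 1) * c_miss + (b - 1) * c_false
                rec(i + a, j + b, acc + cost)

    rec(0, 0, 0.0)
    return best[0]
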