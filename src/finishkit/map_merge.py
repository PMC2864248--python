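"""Merging contig placements from several enzyme maps into one placement.

Optical maps made with different enzymes carry complementary information: a
contig with too few sites for one enzyme may place well on another map.
The merge registers all maps in a common coordinate frame via an *anchor*
contig placed uniquely on every map, then proceeds in four steps:

1. pick the anchor (the longest contig unique on all maps);
2. keep uniquely placed contigs whose distance to the anchor is consistent
   across maps (inconsistent ones are logged and excluded);
3. resolve contigs that are ambiguous on some maps using agreement with
   another map's unique placement or a uniquely agreeing candidate
   combination;
4. add kept placements to the global list in increasing distance from the
   anchor, excluding those whose interval conflicts with an earlier one.

Cross-map coordinate differences are handled by rebasing each map at the
anchor (mirroring it if the anchor was placed in reverse) and rescaling by
the ratio of total map lengths — optical sizing bias is approximately
multiplicative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

from .core_io import RestrictionMap
from .optical_placement import Placement

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedPlacement",
    "MergeParams",
    "select_anchor",
    "normalize_maps",
    "merge_placements",
    "merge_maps",
]


@dataclass
class NormalizedPlacement:
    """A placement expressed in the anchor-rebased, rescaled frame."""

    contig_id: str
    source_map: str
    position: float  # bp from anchor start, modulo genome length if circular
    span: float
    orientation: str
    status: str  # "unique" | "ambiguous"
    contig_length: int = 0

    @property
    def end(self) -> float:
        return self.position + self.span


@dataclass
class MergeParams:
    """Tolerances for cross-map agreement and interval conflicts."""

    t_abs: float = 10_000.0
    t_rel: float = 0.05
    conflict_abs: float = 5_000.0
    conflict_rel: float = 0.20

    def __post_init__(self) -> None:
        if min(self.t_abs, self.t_rel, self.conflict_abs, self.conflict_rel) <= 0:
            raise ValueError("merge tolerances must be positive")


def select_anchor(placement_sets: list[list[Placement]]) -> str:
    """The longest contig placed uniquely on every map (ties by id)."""
    if len(placement_sets) < 2:
        raise ValueError("anchor selection needs at least 2 placement sets")
    common: set[str] | None = None
    lengths: dict[str, int] = {}
    for pls in placement_sets:
        uniq = {p.contig_id for p in pls if p.status == "unique"}
        for p in pls:
            lengths.setdefault(p.contig_id, p.contig_length)
        common = uniq if common is None else (common & uniq)
    if not common:
        raise ValueError(
            "no contig is uniquely placed on all maps; "
            "fall back to single-map scaffolds"
        )
    return max(sorted(common), key=lambda c: (lengths.get(c, 0), ))


def _circ_mod(x: float, L: float | None) -> float:
    return x % L if L else x


def normalize_maps(
    placement_sets: list[list[Placement]],
    maps: list[RestrictionMap],
    anchor: str,
) -> list[list[NormalizedPlacement]]:
    """Rebase every map so the anchor starts at 0 in + orientation.

    A map on which the anchor was placed in reverse is mirrored first.
    Positions are rescaled by (reference map length / this map length),
    the reference being the first map; circular positions are taken modulo
    the rescaled length.
    """
    if len(placement_sets) != len(maps):
        raise ValueError("one placement set per map required")
    L_ref = maps[0].length
    out: list[list[NormalizedPlacement]] = []
    for pls, rmap in zip(placement_sets, maps):
        L = rmap.length
        circular = rmap.topology == "circular"
        anchors = [p for p in pls if p.contig_id == anchor and p.status == "unique"]
        if len(anchors) != 1:
            raise ValueError(f"anchor {anchor!r} not uniquely placed on {rmap.map_id}")
        a = anchors[0]
        mirror = a.orientation == "-"
        scale = L_ref / L
        if mirror:
            a_start = L - a.end
        else:
            a_start = a.start
        normalized: list[NormalizedPlacement] = []
        for p in pls:
            if p.status not in ("unique", "ambiguous"):
                continue
            if mirror:
                start = L - p.end
                orient = "-" if p.orientation == "+" else "+"
            else:
                start = p.start
                orient = p.orientation
            pos = (start - a_start) * scale
            if circular:
                pos = _circ_mod(pos, L_ref)
            normalized.append(
                NormalizedPlacement(
                    p.contig_id, rmap.map_id, pos, p.span * scale, orient,
                    p.status, p.contig_length,
                )
            )
        out.append(normalized)
    return out


def _circ_diff(a: float, b: float, L: float | None) -> float:
    d = abs(a - b)
    if L:
        d = min(d, L - d)
    return d


def _anchor_dist(pos: float, L: float | None) -> float:
    if L:
        return min(pos % L, L - pos % L)
    return abs(pos)


def _tolerance(dist: float, params: MergeParams) -> float:
    return max(params.t_abs, params.t_rel * dist)


def _intervals_conflict(
    a: NormalizedPlacement, b: NormalizedPlacement, L: float | None,
    params: MergeParams,
) -> bool:
    tol = max(params.conflict_abs, params.conflict_rel * min(a.span, b.span))
    shifts = (0.0,) if not L else (-L, 0.0, L)
    for sh in shifts:
        lo = max(a.position + sh, b.position)
        hi = min(a.end + sh, b.end)
        if hi - lo > tol:
            return True
    return False


def merge_placements(
    normalized_sets: list[list[NormalizedPlacement]],
    params: MergeParams | None = None,
    genome_length: float | None = None,
) -> tuple[list[NormalizedPlacement], list[str]]:
    """Combine anchor-rebased placements from several maps.

    Returns the global placement list (sorted by position) and a log of
    exclusions.  A contig unique on several maps must agree within
    ``max(t_abs, t_rel * distance-to-anchor)``; a contig unique on exactly
    one map is kept as-is (this is how a second enzyme rescues contigs with
    few sites for the first); an ambiguous contig is resolved by agreement
    with a unique placement on another map or by a uniquely agreeing
    candidate combination.  Placements are committed nearest-to-anchor
    first, dropping any whose interval conflicts with an earlier one.
    """
    p = params or MergeParams()
    log: list[str] = []

    by_contig: dict[str, list[list[NormalizedPlacement]]] = {}
    for mset in normalized_sets:
        per_map: dict[str, list[NormalizedPlacement]] = {}
        for np_ in mset:
            per_map.setdefault(np_.contig_id, []).append(np_)
        for cid, entries in per_map.items():
            by_contig.setdefault(cid, []).append(entries)

    kept: list[NormalizedPlacement] = []
    for cid in sorted(by_contig):
        groups = by_contig[cid]
        uniques = [g[0] for g in groups if len(g) == 1 and g[0].status == "unique"]
        if uniques:
            chosen = uniques[0]
            consistent = True
            for other in uniques[1:]:
                dist = _anchor_dist(chosen.position, genome_length)
                if _circ_diff(chosen.position, other.position, genome_length) > _tolerance(dist, p):
                    consistent = False
                    log.append(
                        f"{cid}: inconsistent across maps "
                        f"({chosen.source_map}@{chosen.position:.0f} vs "
                        f"{other.source_map}@{other.position:.0f}); excluded"
                    )
                    break
            if consistent:
                kept.append(chosen)
            continue
        # ambiguous everywhere it appears: look for one agreeing combination
        cand_groups = [g for g in groups if g]
        if not cand_groups:
            continue
        if len(cand_groups) == 1:
            log.append(f"{cid}: ambiguous on a single map only; left unplaced")
            continue
        agreeing: list[tuple[NormalizedPlacement, ...]] = []
        for combo in product(*cand_groups):
            ok = True
            for i in range(len(combo)):
                for j in range(i + 1, len(combo)):
                    dist = _anchor_dist(combo[i].position, genome_length)
                    if _circ_diff(
                        combo[i].position, combo[j].position, genome_length
                    ) > _tolerance(dist, p):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                agreeing.append(combo)
        if len(agreeing) == 1:
            kept.append(agreeing[0][0])
        else:
            log.append(
                f"{cid}: {len(agreeing)} agreeing candidate combinations; "
                "left unplaced"
            )

    # step 4: commit nearest-to-anchor first, excluding interval conflicts
    merged: list[NormalizedPlacement] = []
    for np_ in sorted(kept, key=lambda x: (_anchor_dist(x.position, genome_length), x.contig_id)):
        conflict = next(
            (m for m in merged if _intervals_conflict(np_, m, genome_length, p)),
            None,
        )
        if conflict is not None:
            log.append(
                f"{np_.contig_id}: conflicts with earlier placement of "
                f"{conflict.contig_id}; excluded"
            )
            continue
        merged.append(np_)
    merged.sort(key=lambda x: x.position)
    return merged, log


def scaffold_from_merged(
    merged: list[NormalizedPlacement],
    scaffold_id: str = "merged",
    map_length: float | None = None,
) -> "Scaffold":
    """Turn a merged global placement list into a linear scaffold.

    Gaps are the map distances between consecutive placements (possibly
    slightly negative within the conflict tolerance).  On a circular
    genome the junction between the last and first placement is not
    represented (the scaffold is reported linear, as AGP requires).
    """
    from .core_io import Scaffold, ScaffoldPart

    parts = [
        ScaffoldPart(
            np_.contig_id, np_.contig_length or int(np_.span), np_.orientation,
            np_.position, np_.end,
        )
        for np_ in merged
    ]
    gaps = [int(b.position - a.end) for a, b in zip(merged, merged[1:])]
    coverage = None
    if map_length:
        coverage = min(1.0, sum(p.span for p in merged) / map_length)
    return Scaffold(
        id=scaffold_id, parts=parts, gaps=gaps, map_length=int(map_length) if map_length else None,
        coverage_frac=coverage,
    )


def merge_maps(
    placement_sets: list[list[Placement]],
    maps: list[RestrictionMap],
    params: MergeParams | None = None,
) -> tuple[list[NormalizedPlacement], list[str], str]:
    """Convenience wrapper: anchor selection, normalization and merge."""
    anchor = select_anchor(placement_sets)
    normalized = normalize_maps(placement_sets, maps, anchor)
    circular = maps[0].topology == "circular"
    L = float(maps[0].length) if circular else None
    merged, log = merge_placements(normalized, params, genome_length=L)
    return merged, log, anchor
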