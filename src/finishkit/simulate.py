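"""Synthetic genomes, contigs, link evidence, coverage, and noisy maps.

The generator emulates the data a high-coverage short-read bacterial
project hands to a finishing pipeline:

* a circular (or linear) genome of i.i.d. background bases at a target GC,
  optionally carrying GC-distinct islands, into which exact multi-copy
  repeat families are pasted;
* its fragmentation into contigs at repeat boundaries — conservative
  assemblers collapse exact repeat copies into one contig and break the
  unique sequence around them;
* spanning-read link evidence at every true junction, with Poisson support
  counts and optional spurious single-read noise links;
* per-contig read depth proportional to copy number with mild
  multiplicative noise;
* whole-genome ordered restriction maps with fragment-sizing noise, missed
  cuts, false cuts, and a small-fragment detection floor (sub-floor
  fragments merge into a neighbour, as the mapping platform cannot resolve
  them).

All generators are deterministic under their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import LinkRecord, RestrictionMap, SequenceRecord, revcomp
from .optical_placement import digest, merge_small_fragments

__all__ = [
    "ENZYMES",
    "GenomeSpec",
    "RepeatSpec",
    "GcIsland",
    "TruthSegment",
    "TruthLayout",
    "MapNoiseSpec",
    "random_dna",
    "simulate_genome",
    "derive_contigs",
    "tile_contigs",
    "scrub_sites",
    "simulate_links",
    "simulate_coverage",
    "simulate_optical_map",
    "truth_sidecar",
]

# the two enzymes used for the real optical maps this toolbox targets
ENZYMES = {"AflII": "CTTAAG", "NheI": "GCTAGC"}


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """i.i.d. DNA of length n at the given GC fraction."""
    at, gcp = (1 - gc) / 2, gc / 2
    alphabet = np.frombuffer(b"ATGC", dtype=np.uint8)
    idx = rng.choice(4, size=n, p=[at, at, gcp, gcp])
    return alphabet[idx].tobytes().decode("ascii")


@dataclass
class RepeatSpec:
    """One exact repeat family: ``copies`` identical pastes of one unit."""

    family: str
    unit_length: int
    copies: int
    positions: list[int] | None = None  # explicit starts; None = random
    orientations: list[str] | None = None  # per copy; None = random


@dataclass
class GcIsland:
    length: int
    gc: float
    position: int | None = None  # start; None = random


@dataclass
class GenomeSpec:
    length: int
    gc: float = 0.5
    topology: str = "circular"
    repeats: list[RepeatSpec] = field(default_factory=list)
    gc_islands: list[GcIsland] = field(default_factory=list)
    seed: int = 0
    repeat_orientation: str = "random"  # "random" | "forward"

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if sum(r.unit_length * r.copies for r in self.repeats) >= self.length:
            raise ValueError("repeats do not fit in the genome")


@dataclass
class TruthSegment:
    segment_id: str
    kind: str  # "unique" | repeat family id
    start: int
    end: int
    orientation: str  # orientation of the pasted unit ("+" for unique)
    contig_id: str = ""


@dataclass
class TruthLayout:
    """Ground-truth tiling of the genome into unique/repeat segments."""

    topology: str
    length: int
    segments: list[TruthSegment]
    multiplicity: dict[str, int] = field(default_factory=dict)
    links: list[LinkRecord] = field(default_factory=list)


def _place_non_overlapping(
    rng: np.random.Generator,
    length: int,
    wanted: list[int],
    taken: list[tuple[int, int]],
    attempts: int = 1000,
) -> list[int]:
    """Uniform non-overlapping interval starts, avoiding the origin wrap."""
    starts: list[int] = []
    occupied = list(taken)
    for w in wanted:
        for _ in range(attempts):
            s = int(rng.integers(1, length - w - 1))
            if all(s + w <= a or s >= b for a, b in occupied):
                occupied.append((s, s + w))
                starts.append(s)
                break
        else:
            raise RuntimeError(
                f"could not place a {w} bp interval without overlap "
                f"after {attempts} attempts"
            )
    return starts


def simulate_genome(spec: GenomeSpec) -> tuple[SequenceRecord, TruthLayout]:
    """Generate a genome and its ground-truth segment layout.

    Background bases are i.i.d. at the target GC; GC islands overwrite the
    background (before repeats, so repeat copies stay exact); each repeat
    family's unit is generated once and pasted identically at
    non-overlapping positions, in random orientation per copy unless the
    spec pins orientations.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(random_dna(rng, spec.length, spec.gc))

    island_wanted = [isl for isl in spec.gc_islands if isl.position is None]
    auto = _place_non_overlapping(
        rng, spec.length, [i.length for i in island_wanted], []
    ) if island_wanted else []
    it = iter(auto)
    for isl in spec.gc_islands:
        start = isl.position if isl.position is not None else next(it)
        seq[start:start + isl.length] = list(random_dna(rng, isl.length, isl.gc))

    placed: list[tuple[int, int, str, str]] = []  # (start, end, family, orient)
    taken: list[tuple[int, int]] = []
    for rep in spec.repeats:
        unit = random_dna(rng, rep.unit_length, spec.gc)
        if rep.positions is not None:
            starts = list(rep.positions)
        else:
            starts = _place_non_overlapping(
                rng, spec.length, [rep.unit_length] * rep.copies, taken
            )
        for k, s in enumerate(starts):
            if rep.orientations is not None:
                orient = rep.orientations[k]
            elif spec.repeat_orientation == "forward":
                orient = "+"
            else:
                orient = "+" if rng.random() < 0.5 else "-"
            copy = unit if orient == "+" else revcomp(unit)
            seq[s:s + rep.unit_length] = list(copy)
            placed.append((s, s + rep.unit_length, rep.family, orient))
            taken.append((s, s + rep.unit_length))

    placed.sort()
    segments: list[TruthSegment] = []
    cursor = 0
    u = 0
    for s, e, fam, orient in placed:
        if s > cursor:
            u += 1
            segments.append(TruthSegment(f"u{u}", "unique", cursor, s, "+"))
        segments.append(TruthSegment(f"{fam}.{sum(1 for x in segments if x.kind == fam) + 1}", fam, s, e, orient))
        cursor = e
    if cursor < spec.length:
        u += 1
        segments.append(TruthSegment(f"u{u}", "unique", cursor, spec.length, "+"))

    genome = SequenceRecord(
        "genome", "".join(seq), f"{spec.topology} simulated genome {spec.length} bp"
    )
    layout = TruthLayout(spec.topology, spec.length, segments)
    return genome, layout


def _segment_contig_ids(layout: TruthLayout) -> None:
    """Assign contig ids: one per unique segment, one shared per family."""
    fam_ids: dict[str, str] = {}
    for seg in layout.segments:
        if seg.kind == "unique":
            seg.contig_id = seg.segment_id
        else:
            seg.contig_id = fam_ids.setdefault(seg.kind, f"rep_{seg.kind}")


def derive_contigs(
    genome: SequenceRecord,
    layout: TruthLayout,
    base_depth: float = 30.0,
    seed: int = 0,
    depth_cv: float = 0.10,
) -> tuple[list[SequenceRecord], dict[str, float], list[LinkRecord]]:
    """Fragment the genome into contigs at repeat boundaries.

    One contig per unique segment and one per repeat family (the unit
    sequence, forward orientation); on a circular genome the unique
    segments flanking the origin fuse into a single wrap-around contig.
    Coverage is ``base_depth * multiplicity`` with ~``depth_cv``
    multiplicative Gaussian noise; true links join the facing contig ends
    at every segment junction with offset 0.
    """
    rng = np.random.default_rng(seed + 101)
    _segment_contig_ids(layout)
    segs = list(layout.segments)
    circular = layout.topology == "circular"

    wrap_id = None
    if circular and len(segs) >= 2 and segs[0].kind == "unique" and segs[-1].kind == "unique":
        wrap_id = f"{segs[-1].segment_id}{segs[0].segment_id}"
        segs[0].contig_id = wrap_id
        segs[-1].contig_id = wrap_id

    contigs: dict[str, SequenceRecord] = {}
    mult: dict[str, int] = {}
    for seg in segs:
        mult[seg.contig_id] = mult.get(seg.contig_id, 0) + 1
        if seg.contig_id in contigs:
            continue
        if seg.contig_id == wrap_id:
            sseq = genome.seq[segs[-1].start:] + genome.seq[:segs[0].end]
        else:
            sseq = genome.seq[seg.start:seg.end]
            if seg.orientation == "-":
                sseq = revcomp(sseq)  # family contig stored forward
        contigs[seg.contig_id] = SequenceRecord(seg.contig_id, sseq)
    if wrap_id:
        mult[wrap_id] = 1
        # the two wrap pieces are one physical contig used once
    layout.multiplicity = mult

    links: list[LinkRecord] = []
    n = len(segs)
    junctions = range(n if circular else n - 1)
    for j in junctions:
        a, b = segs[j], segs[(j + 1) % n]
        if circular and wrap_id and j == n - 1:
            continue  # junction internal to the wrap contig
        ea = "E" if a.orientation == "+" else "B"
        eb = "B" if b.orientation == "+" else "E"
        links.append(LinkRecord(a.contig_id, ea, b.contig_id, eb, 1, 0))
    layout.links = links
    coverage = {
        cid: float(base_depth * mult[cid] * max(0.05, rng.normal(1.0, depth_cv)))
        for cid in contigs
    }
    return list(contigs.values()), coverage, links


def tile_contigs(
    genome: SequenceRecord,
    n_contigs: int,
    seed: int = 0,
    min_len: int = 15_000,
    flip_prob: float = 0.5,
    boundaries: list[int] | None = None,
) -> list[tuple[SequenceRecord, int, str]]:
    """Cut a genome into consecutive windows, as a fragmented assembly would.

    Returns ``(record, true_start, true_orientation)`` per contig; a
    contig with orientation ``-`` is reported reverse-complemented, so a
    placement pipeline must recover both position and strand.  Window
    boundaries are uniform subject to a minimum contig length, or taken
    from ``boundaries`` (interior cut positions) when given.
    """
    rng = np.random.default_rng(seed + 202)
    L = len(genome.seq)
    if boundaries is not None:
        bounds = [0] + sorted(boundaries) + [L]
    else:
        if n_contigs * min_len > L:
            raise ValueError("genome too short for requested tiling")
        while True:
            cuts = sorted(rng.choice(L, size=n_contigs - 1, replace=False).tolist())
            bounds = [0] + cuts + [L]
            if all(b - a >= min_len for a, b in zip(bounds, bounds[1:])):
                break
    out = []
    for k, (a, b) in enumerate(zip(bounds, bounds[1:])):
        sseq = genome.seq[a:b]
        orient = "-" if rng.random() < flip_prob else "+"
        if orient == "-":
            sseq = revcomp(sseq)
        out.append((SequenceRecord(f"c{k + 1:02d}", sseq), a, orient))
    return out


def scrub_sites(
    seq: str, site: str, rng: np.random.Generator, region: tuple[int, int] | None = None
) -> str:
    """Destroy every occurrence of a recognition site (within a region) by
    mutating its central base; used to build enzyme-poor test segments."""
    lo, hi = region or (0, len(seq))
    s = list(seq)
    mid = len(site) // 2
    bases = "ACGT"
    guard = 0
    while guard < 10_000:
        guard += 1
        window = "".join(s[lo:hi])
        i = window.find(site)
        if i < 0:
            return "".join(s)
        pos = lo + i + mid
        old = s[pos]
        s[pos] = bases[(bases.index(old) + 1 + int(rng.integers(0, 3))) % 4]
    raise RuntimeError("failed to scrub sites")


def simulate_links(
    true_links: list[LinkRecord],
    mean_support: float = 5.0,
    noise_links: int = 0,
    seed: int = 0,
    contig_ends: list[tuple[str, str]] | None = None,
) -> list[LinkRecord]:
    """Dress true links with Poisson support and add spurious noise links.

    Noise links join random non-adjacent end pairs with support 1, so a
    downstream ``min_support >= 2`` filter removes them.
    """
    if mean_support < 1:
        raise ValueError("mean_support must be >= 1")
    rng = np.random.default_rng(seed + 303)
    out = [
        LinkRecord(
            lk.contig_a, lk.end_a, lk.contig_b, lk.end_b,
            max(1, int(rng.poisson(mean_support))), lk.offset_bp,
        )
        for lk in true_links
    ]
    if noise_links:
        if contig_ends is None:
            ids = sorted(
                {lk.contig_a for lk in true_links} | {lk.contig_b for lk in true_links}
            )
            contig_ends = [(cid, e) for cid in ids for e in ("B", "E")]
        seen_keys = {lk.key for lk in true_links}
        made = 0
        guard = 0
        while made < noise_links and guard < 1000 * noise_links:
            guard += 1
            i, j = rng.integers(0, len(contig_ends), size=2)
            ea, eb = contig_ends[int(i)], contig_ends[int(j)]
            if ea == eb:
                continue
            lk = LinkRecord(ea[0], ea[1], eb[0], eb[1], 1, int(rng.integers(-50, 200)))
            if lk.key in seen_keys:
                continue  # each spurious link is a distinct one-read artifact
            seen_keys.add(lk.key)
            out.append(lk)
            made += 1
    return out


def simulate_coverage(
    contigs: list[SequenceRecord],
    multiplicity: dict[str, int],
    base_depth: float = 30.0,
    seed: int = 0,
    depth_cv: float = 0.10,
) -> dict[str, float]:
    """Depth proportional to copy number with multiplicative noise."""
    rng = np.random.default_rng(seed + 404)
    return {
        r.id: float(
            base_depth * multiplicity.get(r.id, 1) * max(0.05, rng.normal(1.0, depth_cv))
        )
        for r in contigs
    }


@dataclass
class MapNoiseSpec:
    """Error model of the optical mapping process."""

    sigma_rel: float = 0.03  # relative fragment-sizing s.d.
    p_miss: float = 0.05  # per-cut miss probability
    false_rate: float = 1.0  # false cuts per 100 kbp
    min_frag: int = 2000  # detection floor, bp
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_miss <= 1:
            raise ValueError("p_miss must be a probability")
        if self.sigma_rel < 0 or self.false_rate < 0 or self.min_frag < 0:
            raise ValueError("noise rates must be >= 0")


def simulate_optical_map(
    genome: SequenceRecord,
    enzyme: str,
    noise: MapNoiseSpec | None = None,
    topology: str = "circular",
    map_id: str | None = None,
) -> RestrictionMap:
    """Digest a genome in silico and corrupt the result like an optical map.

    True cuts are dropped with ``p_miss``; false cuts arrive as a Poisson
    process at ``false_rate`` per 100 kbp; every fragment length is
    resampled as round(Normal(e, sigma_rel * e)) clamped at 1; fragments
    below ``min_frag`` merge into their smaller neighbour.
    """
    noise = noise or MapNoiseSpec()
    site = ENZYMES.get(enzyme, enzyme)
    rng = np.random.default_rng(noise.seed + 505)
    L = len(genome.seq)
    dg = digest(genome.seq, site, topology)
    cuts = list(dg.cut_positions)
    if len(cuts) < 2:
        import warnings

        warnings.warn(f"site {site} occurs < 2 times; trivial map", stacklevel=2)
    if noise.p_miss > 0:
        cuts = [c for c in cuts if rng.random() >= noise.p_miss]
    n_false = rng.poisson(noise.false_rate * L / 100_000.0)
    cuts.extend(int(rng.integers(0, L)) for _ in range(n_false))
    cuts = sorted(set(cuts))
    if topology == "circular":
        if not cuts:
            frags = [L]
        else:
            frags = [b - a for a, b in zip(cuts, cuts[1:])]
            frags.append(L - cuts[-1] + cuts[0])
    else:
        bounds = [0] + cuts + [L]
        frags = [b - a for a, b in zip(bounds, bounds[1:])]
    frags = [f for f in frags if f > 0]
    if noise.sigma_rel > 0:
        frags = [
            max(1, int(round(rng.normal(f, noise.sigma_rel * f)))) for f in frags
        ]
    # track which cut survives as the start of fragment 0 through merging,
    # so the map's coordinate origin is known exactly for truth checks
    starts = list(cuts) if (topology == "circular" and cuts) else [0] * len(frags)
    if noise.min_frag > 0:
        frags, starts = _merge_small_tracked(
            frags, starts, noise.min_frag, circular=(topology == "circular")
        )
    rmap = RestrictionMap(map_id or f"map_{enzyme}", enzyme, site, topology, frags)
    # genome coordinate of map position 0 (circular maps have an arbitrary
    # origin: the first retained cut)
    rmap.origin_bp = starts[0] if (topology == "circular" and starts) else 0
    return rmap


def _merge_small_tracked(
    frags: list[int], starts: list[int], floor: int, circular: bool
) -> tuple[list[int], list[int]]:
    """Same merge rule as :func:`merge_small_fragments`, but carrying each
    fragment's start-cut genome coordinate through the merges."""
    frags = list(frags)
    starts = list(starts)
    while len(frags) > 1:
        small = [(f, i) for i, f in enumerate(frags) if f < floor]
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
        if tgt == right:
            starts[tgt] = starts[i]
        del frags[i], starts[i]
    return frags, starts


def truth_sidecar(spec: GenomeSpec, layout: TruthLayout) -> str:
    """JSON sidecar recording the generating spec and the true layout."""
    doc = {
        "spec": asdict(spec),
        "layout": {
            "topology": layout.topology,
            "length": layout.length,
            "segments": [asdict(s) for s in layout.segments],
            "multiplicity": layout.multiplicity,
            "links": [
                [lk.contig_a, lk.end_a, lk.contig_b, lk.end_b, lk.support, lk.offset_bp]
                for lk in layout.links
            ],
        },
    }
    return json.dumps(doc, indent=2)
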