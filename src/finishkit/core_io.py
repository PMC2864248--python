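"""Readers and writers for the on-disk formats the toolkit touches.

Formats handled here:

* FASTA for contig and genome sequences (via Biopython).
* A small tabular format for whole-genome ordered restriction maps:
  a header line ``#map_id<TAB>enzyme<TAB>site<TAB>topology`` followed by
  one fragment size (bp) per line, in map order.
* A 6-column TSV for contig-link evidence
  (``contig_a end_a contig_b end_b support offset_bp``).
* PAF for read-to-contig alignments (columns 1-12).
* AGP v2.0 for scaffold layouts.

All in-memory coordinates are 0-based half-open; AGP output is 1-based
inclusive as the format requires.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SequenceRecord",
    "RestrictionMap",
    "LinkRecord",
    "PafAlignment",
    "ScaffoldPart",
    "Scaffold",
    "read_fasta",
    "write_fasta",
    "read_restriction_map",
    "write_restriction_map",
    "read_fragment_list",
    "read_links_tsv",
    "write_links_tsv",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "read_alignments_paf",
    "write_scaffold_agp",
    "read_scaffold_agp",
    "revcomp",
    "gc_fraction",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases only (N excluded from denominator).

    Returns 0.0 for a window with no unambiguous bases.
    """
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class SequenceRecord:
    """A named DNA sequence (uppercase A/C/G/T/N)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.seq) < 1:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


_VALID_BASES = frozenset("ACGTN")


def _normalize_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FormatError(
            f"sequence {rec_id!r} contains non-DNA characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased and U is normalized to T.  Duplicate ids and
    empty sequences are format errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FormatError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, _normalize_seq(str(rec.seq), rec.id), desc))
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class RestrictionMap:
    """An ordered whole-genome restriction map for a single enzyme.

    ``fragments`` is the ordered list of restriction-fragment lengths in bp.
    A circular map with k cut sites has exactly k fragments; a linear map
    with k sites has k+1 (the two terminal fragments end at the molecule
    ends, not at cut sites).
    """

    map_id: str
    enzyme: str
    site: str
    topology: str  # "linear" | "circular"
    fragments: list[int]

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise FormatError(f"unknown topology {self.topology!r}")
        if not self.fragments:
            raise FormatError(f"map {self.map_id!r} has no fragments")
        for f in self.fragments:
            if int(f) != f or f <= 0:
                raise FormatError(f"map {self.map_id!r}: non-positive fragment {f!r}")
        self.fragments = [int(f) for f in self.fragments]

    @property
    def length(self) -> int:
        return sum(self.fragments)

    def cut_positions(self) -> list[int]:
        """Positions of cut sites along the map, in bp from the map start.

        For a circular map the first cut is at 0 by convention (every
        fragment boundary is a cut).  For a linear map the molecule ends at
        positions 0 and ``length`` are *not* cut sites; the k interior
        boundaries are.
        """
        pos, acc = [], 0
        if self.topology == "circular":
            for f in self.fragments:
                pos.append(acc)
                acc += f
            return pos
        for f in self.fragments[:-1]:
            acc += f
            pos.append(acc)
        return pos


def read_restriction_map(path: str | os.PathLike) -> RestrictionMap:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}: restriction map must start with a '#' header")
        parts = header[1:].split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}: header needs map_id, enzyme, site, topology")
        map_id, enzyme, site, topology = parts
        fragments: list[int] = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                frag = int(line)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad fragment size {line!r}") from exc
            if frag <= 0:
                raise FormatError(f"{path}:{ln}: non-positive fragment size {frag}")
            fragments.append(frag)
    return RestrictionMap(map_id, enzyme, site, topology, fragments)


def write_restriction_map(rmap: RestrictionMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{rmap.map_id}\t{rmap.enzyme}\t{rmap.site}\t{rmap.topology}\n")
        for f in rmap.fragments:
            fh.write(f"{f}\n")


def read_fragment_list(path: str | os.PathLike, map_id: str = "map",
                       enzyme: str = "", site: str = "",
                       topology: str = "linear") -> RestrictionMap:
    """Convenience reader for a bare whitespace-separated fragment-size list."""
    with open(path) as fh:
        tokens = fh.read().split()
    try:
        fragments = [int(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer fragment size") from exc
    return RestrictionMap(map_id, enzyme, site, topology, fragments)


_ENDS = ("B", "E")


@dataclass(frozen=True)
class LinkRecord:
    """Evidence that two contig ends are adjacent in the genome.

    Ends are named on the forward strand: B = beginning, E = end.
    ``offset_bp`` is the implied distance between the two ends: negative
    means the contigs overlap, positive means a gap, 0 means abutting.
    """

    contig_a: str
    end_a: str
    contig_b: str
    end_b: str
    support: int
    offset_bp: int = 0

    def __post_init__(self) -> None:
        if self.end_a not in _ENDS or self.end_b not in _ENDS:
            raise FormatError(f"link {self}: ends must be B or E")
        if self.support < 1:
            raise FormatError(f"link {self}: support must be >= 1")
        if (self.contig_a, self.end_a) == (self.contig_b, self.end_b):
            raise FormatError(
                f"link joins contig end {self.contig_a}.{self.end_a} to itself"
            )

    @property
    def key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """Orientation-free canonical end-pair key for aggregation."""
        a, b = (self.contig_a, self.end_a), (self.contig_b, self.end_b)
        return (a, b) if a <= b else (b, a)

    def other_end(self, end: tuple[str, str]) -> tuple[str, str]:
        a, b = (self.contig_a, self.end_a), (self.contig_b, self.end_b)
        return b if end == a else a


def read_links_tsv(path: str | os.PathLike) -> list[LinkRecord]:
    links: list[LinkRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}:{ln}: expected 6 tab-separated columns")
            ca, ea, cb, eb, sup, off = cols
            try:
                links.append(LinkRecord(ca, ea, cb, eb, int(sup), int(off)))
            except FormatError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad integer field") from exc
    return links


def write_links_tsv(links: list[LinkRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for lk in links:
            fh.write(
                f"{lk.contig_a}\t{lk.end_a}\t{lk.contig_b}\t{lk.end_b}"
                f"\t{lk.support}\t{lk.offset_bp}\n"
            )


def read_coverage_tsv(path: str | os.PathLike) -> dict[str, float]:
    """Read a 2-column (contig_id, mean depth) TSV into a dict."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns")
            cid, depth = cols
            try:
                d = float(depth)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad depth {depth!r}") from exc
            if d < 0:
                raise FormatError(f"{path}:{ln}: negative depth")
            table[cid] = d
    return table


def write_coverage_tsv(coverage: dict[str, float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for cid, depth in coverage.items():
            fh.write(f"{cid}\t{depth:.3f}\n")


@dataclass(frozen=True)
class PafAlignment:
    """One read-to-contig alignment (PAF columns 1-12, 0-based half-open)."""

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    strand: str
    contig_id: str
    contig_len: int
    contig_start: int
    contig_end: int
    matches: int = 0
    block_len: int = 0
    mapq: int = 0


def read_alignments_paf(path: str | os.PathLike) -> list[PafAlignment]:
    out: list[PafAlignment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{ln}: PAF line has fewer than 12 columns")
            if cols[4] not in "+-":
                raise FormatError(f"{path}:{ln}: bad strand {cols[4]!r}")
            try:
                out.append(
                    PafAlignment(
                        read_id=cols[0],
                        read_len=int(cols[1]),
                        read_start=int(cols[2]),
                        read_end=int(cols[3]),
                        strand=cols[4],
                        contig_id=cols[5],
                        contig_len=int(cols[6]),
                        contig_start=int(cols[7]),
                        contig_end=int(cols[8]),
                        matches=int(cols[9]),
                        block_len=int(cols[10]),
                        mapq=int(cols[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad integer field") from exc
    return out


@dataclass
class ScaffoldPart:
    """One placed contig inside a scaffold."""

    contig_id: str
    length: int
    orientation: str  # "+" | "-"
    map_start: float | None = None
    map_end: float | None = None
    score: float | None = None


@dataclass
class Scaffold:
    """Ordered, oriented contig list with per-junction gap estimates.

    ``gaps[i]`` is the estimated gap (bp) between ``parts[i]`` and
    ``parts[i+1]``; ``None`` means unknown.  Raw gaps may be negative
    (slight overlap within tolerance); they are clamped to 0 only when
    written as AGP.
    """

    id: str
    parts: list[ScaffoldPart] = field(default_factory=list)
    gaps: list[int | None] = field(default_factory=list)
    map_id: str | None = None
    map_length: int | None = None
    coverage_frac: float | None = None
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.parts and len(self.gaps) != len(self.parts) - 1:
            raise ValueError(
                f"scaffold {self.id!r}: {len(self.parts)} parts need "
                f"{len(self.parts) - 1} gaps, got {len(self.gaps)}"
            )

    @property
    def span(self) -> int:
        total = sum(p.length for p in self.parts)
        total += sum(self._agp_gap(g) for g in self.gaps)
        return total

    @staticmethod
    def _agp_gap(gap: int | None) -> int:
        if gap is None:
            return 100
        return max(0, int(round(gap)))


def write_scaffold_agp(scaffolds: list[Scaffold], path: str | os.PathLike) -> None:
    """Write scaffolds as AGP v2.0.

    Component lines are type W with 1-based inclusive coordinates; gaps are
    type N with the estimated size (clamped at 0 -> component lines become
    adjacent) or type U with size 100 when the size is unknown.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for sc in scaffolds:
            obj_pos = 0  # 0-based running coordinate
            part_no = 0
            for i, part in enumerate(sc.parts):
                part_no += 1
                beg, end = obj_pos + 1, obj_pos + part.length
                fh.write(
                    f"{sc.id}\t{beg}\t{end}\t{part_no}\tW\t{part.contig_id}"
                    f"\t1\t{part.length}\t{part.orientation}\n"
                )
                obj_pos = end
                if i < len(sc.parts) - 1:
                    gap = sc.gaps[i]
                    if gap is None:
                        size, gtype = 100, "U"
                    else:
                        size, gtype = max(0, int(round(gap))), "N"
                    if size > 0:
                        part_no += 1
                        fh.write(
                            f"{sc.id}\t{obj_pos + 1}\t{obj_pos + size}\t{part_no}"
                            f"\t{gtype}\t{size}\tscaffold\tyes\tmap\n"
                        )
                        obj_pos += size


def read_scaffold_agp(path: str | os.PathLike) -> list[Scaffold]:
    """Re-parse an AGP v2.0 file written by :func:`write_scaffold_agp`.

    N gaps come back with their size, U gaps as ``None`` (unknown), and two
    adjacent W lines as a gap of 0.
    """
    _NO_GAP = object()
    scaffolds: dict[str, Scaffold] = {}
    pending_gap: dict[str, object] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{ln}: AGP line has fewer than 9 columns")
            obj = cols[0]
            sc = scaffolds.get(obj)
            if sc is None:
                sc = Scaffold(id=obj)
                scaffolds[obj] = sc
                pending_gap[obj] = _NO_GAP
            ctype = cols[4]
            if ctype == "W":
                comp_id = cols[5]
                length = int(cols[7]) - int(cols[6]) + 1
                orient = cols[8]
                if sc.parts:
                    gap = pending_gap[obj]
                    sc.gaps.append(0 if gap is _NO_GAP else gap)
                sc.parts.append(ScaffoldPart(comp_id, length, orient))
                pending_gap[obj] = _NO_GAP
            elif ctype in ("N", "U"):
                size = int(cols[5])
                pending_gap[obj] = None if ctype == "U" else size
            else:
                raise FormatError(f"{path}:{ln}: unsupported AGP component type {ctype!r}")
    return list(scaffolds.values())
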