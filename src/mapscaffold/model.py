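"""Core domain types shared across the scaffolding pipeline.

Coordinate conventions
----------------------
All interval coordinates are 0-based, half-open, in base pairs.  Map
positions are 0-based bp on the chromosome coordinate system of the
virtual map.  A contig has two gap-facing ends, ``low`` (coordinate 0)
and ``high`` (coordinate ``length``); a mate-pair link constrains one
end of each of two contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

LOW = "low"
HIGH = "high"

#: Recognised marker sources in a virtual map.
MARKER_SOURCES = frozenset({"FISH", "linkage", "synteny", "unknown"})


@dataclass(frozen=True)
class Marker:
    """A map point: a locus with a chromosome and a bp position.

    ``map_pos`` is the marker's position on the map coordinate system
    (chromosome bp); pseudo mate-pair separations are differences of
    these positions.
    """

    marker_id: str
    chromosome: str
    map_pos: int
    gene_name: Optional[str] = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.map_pos < 0:
            raise ValueError(f"marker {self.marker_id}: map_pos must be >= 0")
        if not self.chromosome:
            raise ValueError(f"marker {self.marker_id}: empty chromosome")


@dataclass(frozen=True)
class Placement:
    """A marker's best alignment onto a contig (0-based half-open)."""

    marker_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    score: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"placement of {self.marker_id}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"placement of {self.marker_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class LibrarySpec:
    """A mate-pair library: an insert-size range and a priority.

    Priority 1 is highest; the scaffolder applies lower-numbered
    priorities first so their joins win conflicts.  The mean insert is
    the midpoint of the range.
    """

    name: str
    insert_min: int
    insert_max: int
    priority: int

    def __post_init__(self) -> None:
        if not (0 < self.insert_min < self.insert_max):
            raise ValueError(
                f"library {self.name}: need 0 < insert_min < insert_max, "
                f"got [{self.insert_min}, {self.insert_max}]"
            )
        if self.priority < 1:
            raise ValueError(f"library {self.name}: priority must be >= 1")

    @property
    def insert_mean(self) -> int:
        return (self.insert_min + self.insert_max) // 2

    @property
    def insert_spread(self) -> int:
        return self.insert_max - self.insert_min


@dataclass(frozen=True)
class PseudoPair:
    """Two same-chromosome markers treated as mates of a virtual fragment.

    ``marker_lo`` has the smaller map position; ``separation`` is the
    map-position difference and must fall inside the library's bin.
    """

    marker_lo: str
    marker_hi: str
    separation: int
    library: str


@dataclass(frozen=True)
class Link:
    """One mate-pair constraint between two contig ends.

    ``tail_a``/``tail_b`` are the distances from each read's outer
    position to the gap-facing end of its contig, so the implied gap is
    ``insert_mean - tail_a - tail_b`` (negative for overlapping
    contigs).  ``read_a``/``read_b`` are the read or marker identifiers,
    kept for interop file export.
    """

    library: str
    priority: int
    insert_mean: int
    contig_a: str
    end_a: str
    tail_a: int
    contig_b: str
    end_b: str
    tail_b: int
    read_a: str = ""
    read_b: str = ""

    def __post_init__(self) -> None:
        if self.contig_a == self.contig_b:
            raise ValueError(f"link {self.read_a}/{self.read_b}: contigs must differ")
        if self.end_a not in (LOW, HIGH) or self.end_b not in (LOW, HIGH):
            raise ValueError("link ends must be 'low' or 'high'")
        if self.tail_a < 0 or self.tail_b < 0:
            raise ValueError("link tails must be >= 0")


@dataclass(frozen=True)
class Bundle:
    """All links supporting the same oriented contig-pair join.

    The contig pair is canonical (``contig_a < contig_b``
    lexicographically); ``gap`` is the median of member link gaps and
    ``tolerance`` the slack allowed when checking the join against an
    existing layout.
    """

    contig_a: str
    end_a: str
    contig_b: str
    end_b: str
    priority: int
    weight: int
    gap: int
    tolerance: int = 1000

    def __post_init__(self) -> None:
        if self.contig_a >= self.contig_b:
            raise ValueError("bundle pair must be canonical (contig_a < contig_b)")
        if self.weight < 1:
            raise ValueError("bundle weight must be >= 1")


@dataclass(frozen=True)
class ContigPlacement:
    """A contig's slot in a scaffold: offset of its leftmost base and
    orientation ('+' forward, '-' reverse-complemented)."""

    contig_id: str
    offset: int
    orientation: str
    length: int


@dataclass
class Scaffold:
    """An ordered, oriented run of contigs with inter-contig gaps.

    Singleton contigs are 1-contig scaffolds.  ``span`` is the total
    extent including gaps, the quantity N50 statistics are computed
    over.
    """

    scaffold_id: str
    placements: list[ContigPlacement] = field(default_factory=list)

    @property
    def n_contigs(self) -> int:
        return len(self.placements)

    @property
    def span(self) -> int:
        return max(p.offset + p.length for p in self.placements)

    @property
    def gaps(self) -> list[int]:
        """Gaps between consecutive contigs (negative = implied overlap)."""
        out = []
        for prev, nxt in zip(self.placements, self.placements[1:]):
            out.append(nxt.offset - (prev.offset + prev.length))
        return out
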