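"""Pseudo mate-pair links from non-sequence map data.

A virtual genome map assigns markers bp positions on chromosomes.  Every
same-chromosome marker pair whose map separation falls inside one of a
set of distance bins is treated as a virtual long-insert fragment whose
"reads" are the two markers; once each marker is located on a contig by
alignment, the pair becomes an ordinary mate-pair link between two
contigs, at map scale (megabases rather than kilobases).

Distance bins start well above the positional imprecision of the map
(FISH localisation is only good to a few megabases), so a pair's marker
order is trustworthy even when individual positions are noisy.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping

import numpy as np

from .model import HIGH, LOW, LibrarySpec, Link, Marker, Placement, PseudoPair

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("marker_id", "chromosome", "map_pos")


def parse_map_table(path) -> list[Marker]:
    """Parse a virtual-map TSV into Markers, preserving file order.

    The file must have a header row with at least ``marker_id``,
    ``chromosome`` and ``map_pos`` columns; ``gene_name`` and ``source``
    are optional.

    Raises
    ------
    ValueError
        on a missing column, a duplicate marker id (naming the id), or
        a non-numeric map position (naming the line number).
    """
    markers: list[Marker] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"map table {path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            mid = row["marker_id"]
            if mid in seen:
                raise ValueError(f"map table {path}: duplicate marker_id {mid!r}")
            seen.add(mid)
            try:
                pos = int(row["map_pos"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"map table {path}, line {lineno}: non-numeric map_pos "
                    f"{row['map_pos']!r}"
                ) from None
            markers.append(
                Marker(
                    marker_id=mid,
                    chromosome=row["chromosome"],
                    map_pos=pos,
                    gene_name=row.get("gene_name") or None,
                    source=row.get("source") or "unknown",
                )
            )
    return markers


def psl_score(matches: int, mis_matches: int, rep_matches: int,
              q_num_insert: int, t_num_insert: int) -> int:
    """BLAT web-style alignment score.

    ``matches + repMatches - misMatches - qNumInsert - tNumInsert``.
    """
    return matches + rep_matches - mis_matches - q_num_insert - t_num_insert


def load_placements(path) -> dict[str, Placement]:
    """Select each marker's best alignment from a PSL file.

    Keeps, per marker (PSL ``qName``), the hit maximising :func:`psl_score`.
    A marker whose best score is tied across distinct contigs is dropped
    as ambiguous (logged); ties on the same contig keep the first hit in
    file order.  Target coordinates are used as-is (PSL is already
    0-based half-open).

    The optional 5-line psLayout header is skipped.  Returns a mapping
    ``marker_id -> Placement``; markers absent from the file simply have
    no entry.
    """
    # marker -> (current best placement, tied-across-contigs flag); the
    # flag is reset whenever a strictly better hit arrives
    best: dict[str, tuple[Placement, bool]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] and not fields[0].lstrip("-").isdigit():
                # psLayout header block (first 5 lines at most)
                if lineno <= 5:
                    continue
                raise ValueError(f"PSL {path}, line {lineno}: malformed record")
            if len(fields) < 17:
                if lineno <= 5:  # the dashed separator line of the header
                    continue
                raise ValueError(
                    f"PSL {path}, line {lineno}: expected 21 columns, got {len(fields)}"
                )
            try:
                matches, mis, rep = int(fields[0]), int(fields[1]), int(fields[2])
                q_ins, t_ins = int(fields[4]), int(fields[6])
                strand = fields[8][-1]  # last char is target strand for translated PSL
                qname = fields[9]
                tname = fields[13]
                t_start, t_end = int(fields[15]), int(fields[16])
            except (ValueError, IndexError):
                raise ValueError(f"PSL {path}, line {lineno}: malformed record") from None
            score = psl_score(matches, mis, rep, q_ins, t_ins)
            hit = Placement(qname, tname, t_start, t_end,
                            "+" if strand == "+" else "-", score)
            entry = best.get(qname)
            if entry is None or score > entry[0].score:
                best[qname] = (hit, False)
            elif score == entry[0].score and hit.contig_id != entry[0].contig_id:
                best[qname] = (entry[0], True)
            # equal score on the same contig: keep the first (file order)
    ambiguous = sorted(m for m, (_, tied) in best.items() if tied)
    if ambiguous:
        logger.info("dropped %d marker(s) with tied best hits on distinct contigs: %s",
                    len(ambiguous), ", ".join(ambiguous))
    return {m: p for m, (p, tied) in best.items() if not tied}


def make_pseudo_libraries(d_start: int, d_end: int, d_step: int,
                          priority: int = 2) -> list[LibrarySpec]:
    """Build distance-binned pseudo mate-pair library specs.

    One library per distance ``d`` in ``d_start, d_start + d_step, ...,
    d_end``; library ``d`` covers separations in ``[d - d_step/2,
    d + d_step/2)``, so bins are disjoint and the mean insert is ``d``.
    The default span of 5-10 Mb in 1 Mb steps gives 6 libraries.
    """
    if d_step <= 0:
        raise ValueError(f"d_step must be positive, got {d_step}")
    if d_start > d_end:
        raise ValueError(f"d_start ({d_start}) must be <= d_end ({d_end})")
    half = d_step // 2
    libs = []
    for d in range(d_start, d_end + 1, d_step):
        if d % 1_000_000 == 0:
            name = f"map{d // 1_000_000}M"
        else:
            name = f"map{d}"
        libs.append(LibrarySpec(name, d - half, d + half, priority))
    return libs


def _check_disjoint(libraries: Iterable[LibrarySpec]) -> list[LibrarySpec]:
    libs = sorted(libraries, key=lambda l: l.insert_min)
    for a, b in zip(libs, libs[1:]):
        if b.insert_min < a.insert_max:
            raise ValueError(
                f"library bins overlap: {a.name} [{a.insert_min},{a.insert_max}) "
                f"and {b.name} [{b.insert_min},{b.insert_max})"
            )
    return libs


def enumerate_pseudo_pairs(markers: Iterable[Marker],
                           libraries: Iterable[LibrarySpec]) -> list[PseudoPair]:
    """Enumerate every same-chromosome marker pair falling in a bin.

    For each unordered pair of markers on the same chromosome, if the
    absolute map-position difference lies in some library's
    ``[insert_min, insert_max)`` bin, exactly one :class:`PseudoPair` is
    emitted for that library; pairs outside all bins are omitted.  Bins
    must be disjoint.  Output order is deterministic (chromosome, then
    position), independent of marker input order.
    """
    libs = _check_disjoint(libraries)
    if not libs:
        return []
    lo_edge = libs[0].insert_min
    hi_edge = libs[-1].insert_max
    edges = np.array([l.insert_min for l in libs] + [libs[-1].insert_max])

    by_chrom: dict[str, list[Marker]] = defaultdict(list)
    for m in markers:
        by_chrom[m.chromosome].append(m)

    pairs: list[PseudoPair] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: (m.map_pos, m.marker_id))
        pos = np.array([m.map_pos for m in ms], dtype=np.int64)
        # for marker i, candidate partners j > i have pos[j] - pos[i] in
        # [lo_edge, hi_edge); find the window by binary search
        j_lo = np.searchsorted(pos, pos + lo_edge, side="left")
        j_hi = np.searchsorted(pos, pos + hi_edge, side="left")
        for i, m in enumerate(ms):
            for j in range(max(j_lo[i], i + 1), j_hi[i]):
                sep = int(pos[j] - pos[i])
                k = int(np.searchsorted(edges, sep, side="right")) - 1
                if k < 0 or k >= len(libs):
                    continue
                lib = libs[k]
                if not (lib.insert_min <= sep < lib.insert_max):
                    continue  # separation falls between two non-adjacent bins
                pairs.append(PseudoPair(m.marker_id, ms[j].marker_id, sep, lib.name))
    return pairs


def pairs_to_links(pairs: Iterable[PseudoPair],
                   placements: Mapping[str, Placement],
                   libraries: Iterable[LibrarySpec],
                   contig_lengths: Mapping[str, int]) -> tuple[list[Link], Counter]:
    """Turn placed pseudo pairs into inter-contig mate-pair links.

    The lower-map-position marker is treated as read 1, oriented toward
    increasing map coordinate; the higher marker as read 2, oriented
    toward decreasing map coordinate (innie/FR convention).  Composed
    with the placement strand this determines which contig end each
    virtual read faces.  The pair's actual map separation is used as the
    link's insert size, giving per-pair gap estimates rather than a
    per-library constant.

    Pairs with an unplaced (or ambiguity-dropped) marker are skipped as
    ``unplaced``; pairs whose markers land on one contig as
    ``intra_contig``.  Returns ``(links, skip_report)`` with
    ``len(links) + sum(skips) == number of pairs``.
    """
    lib_by_name = {l.name: l for l in libraries}
    links: list[Link] = []
    skips: Counter = Counter()
    for pair in pairs:
        p_lo = placements.get(pair.marker_lo)
        p_hi = placements.get(pair.marker_hi)
        if p_lo is None or p_hi is None:
            skips["unplaced"] += 1
            continue
        if p_lo.contig_id == p_hi.contig_id:
            skips["intra_contig"] += 1
            continue
        lib = lib_by_name[pair.library]
        end_a, tail_a = _facing_end(p_lo, toward_increasing=True,
                                    contig_len=contig_lengths[p_lo.contig_id])
        end_b, tail_b = _facing_end(p_hi, toward_increasing=False,
                                    contig_len=contig_lengths[p_hi.contig_id])
        links.append(Link(
            library=lib.name, priority=lib.priority, insert_mean=pair.separation,
            contig_a=p_lo.contig_id, end_a=end_a, tail_a=tail_a,
            contig_b=p_hi.contig_id, end_b=end_b, tail_b=tail_b,
            read_a=pair.marker_lo, read_b=pair.marker_hi,
        ))
    return links, skips


def _facing_end(placement: Placement, toward_increasing: bool,
                contig_len: int) -> tuple[str, int]:
    """Which contig end a map-oriented virtual read faces, and its tail.

    A read pointing toward increasing map coordinate faces the contig's
    high end when the marker aligned on '+', the low end on '-'; a read
    pointing toward decreasing map coordinate is the mirror image.
    """
    faces_high = (placement.strand == "+") == toward_increasing
    if faces_high:
        return HIGH, contig_len - placement.start
    return LOW, placement.end
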