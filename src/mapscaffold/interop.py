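"""Best-effort writers for legacy Bambus scaffolder input files.

Bambus consumes a *mates* file (library insert ranges plus read
pairings) and a TIGR-style *contig* file (read placements within each
contig).  These writers emit that structure deterministically; they are
validated by round-trip parsing, not against the original binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import LibrarySpec, Link


@dataclass(frozen=True)
class ReadPosition:
    """One read's placement on a contig, for the contig-file writer."""

    read_id: str
    contig_id: str
    start: int  # 0-based leftmost
    end: int
    strand: str  # '+' or '-'


def write_bambus_mates(links: Iterable[Link],
                       libraries: Iterable[LibrarySpec], path) -> None:
    """Write a Bambus mates file.

    One ``library <name> <min> <max>`` line per library (lexicographic),
    then one ``<read1> <read2> <library>`` line per link, sorted, so two
    runs over the same data are byte-identical.
    """
    libs = sorted(libraries, key=lambda l: l.name)
    known = {l.name for l in libs}
    pair_lines = []
    for link in links:
        if link.library not in known:
            raise ValueError(f"link {link.read_a}/{link.read_b} references "
                             f"unknown library {link.library!r}")
        pair_lines.append(f"{link.read_a}\t{link.read_b}\t{link.library}")
    with open(path, "w") as fh:
        for lib in libs:
            fh.write(f"library\t{lib.name}\t{lib.insert_min}\t{lib.insert_max}\n")
        for line in sorted(pair_lines):
            fh.write(line + "\n")


def write_bambus_contig(reads: Iterable[ReadPosition],
                        contig_lengths: Mapping[str, int], path) -> None:
    """Write a TIGR .contig-style file of read placements.

    Per contig: a ``##<contig> <nreads> <length> bases`` header, then a
    ``#<read>(<offset>) [<RC?>] <len> bases`` line per read; contigs and
    reads are sorted so output is deterministic.
    """
    by_contig: dict[str, list[ReadPosition]] = {}
    for r in reads:
        if r.contig_id not in contig_lengths:
            raise ValueError(f"read {r.read_id} placed on unknown contig "
                             f"{r.contig_id!r}")
        by_contig.setdefault(r.contig_id, []).append(r)
    with open(path, "w") as fh:
        for contig in sorted(by_contig):
            members = sorted(by_contig[contig], key=lambda r: (r.start, r.read_id))
            fh.write(f"##{contig} {len(members)} {contig_lengths[contig]} bases\n")
            for r in members:
                rc = "RC" if r.strand == "-" else ""
                fh.write(f"#{r.read_id}({r.start}) [{rc}] {r.end - r.start} bases\n")
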