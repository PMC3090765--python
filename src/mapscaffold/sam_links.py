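"""Inter-contig links from paired-end read mappings in SAM format.

A retained pair must have both mates mapped, each with at most
``max_mismatches`` mismatches (NM tag) and a unique mapping; mates on
one contig carry no inter-contig information and are tallied separately.
Each retained inter-contig pair becomes one :class:`~.model.Link` under
the FR (innie) assumption: a forward-strand mate faces the
high-coordinate end of its contig, a reverse-strand mate the low end.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

import pysam

from .model import HIGH, LOW, LibrarySpec, Link

logger = logging.getLogger(__name__)


def parse_sam_pairs(path, library: LibrarySpec,
                    max_mismatches: int = 3) -> tuple[list[Link], Counter]:
    """Extract inter-contig mate-pair links from a SAM file.

    Parameters
    ----------
    path
        SAM file with ``@SQ`` header lines (contig lengths are needed
        for tail arithmetic).  Any record order is accepted; mates are
        paired by query name.
    library
        Insert-size range and priority assigned to every emitted link.
    max_mismatches
        A pair is excluded when either mate's NM tag exceeds this
        (a missing NM tag counts as 0 mismatches, logged once).

    Returns
    -------
    (links, skip_report)
        ``skip_report`` tallies excluded pairs by reason (``unmapped``,
        ``multimap``, ``mismatch``, ``intra_contig``, ``orphan``);
        retained + excluded equals the number of pairs seen.

    Notes
    -----
    Multi-mapping is detected as MAPQ 0 on a primary record or the
    presence of a secondary/supplementary record for that mate — a
    mapper-independent proxy for reads aligning to multiple locations.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        if sam.nreferences == 0:
            raise ValueError(f"{path}: SAM has no @SQ lines; contig lengths required")
        lengths = dict(zip(sam.references, sam.lengths))
        # mates[qname][0|1] -> primary record; multi[qname] -> set of mate
        # indices seen in secondary/supplementary records
        mates: dict[str, dict[int, pysam.AlignedSegment]] = defaultdict(dict)
        multi: dict[str, set[int]] = defaultdict(set)
        missing_nm = False
        for rec in sam:
            idx = 1 if rec.is_read2 else 0
            if rec.is_secondary or rec.is_supplementary:
                multi[rec.query_name].add(idx)
                continue
            mates[rec.query_name][idx] = rec

    links: list[Link] = []
    skips: Counter = Counter()
    for qname in sorted(mates):  # record-order independent
        pair = mates[qname]
        if len(pair) < 2:
            skips["orphan"] += 1
            continue
        a, b = pair[0], pair[1]
        if a.is_unmapped or b.is_unmapped:
            skips["unmapped"] += 1
            continue
        if multi.get(qname) or a.mapping_quality == 0 or b.mapping_quality == 0:
            skips["multimap"] += 1
            continue
        nm = []
        for rec in (a, b):
            if rec.has_tag("NM"):
                nm.append(rec.get_tag("NM"))
            else:
                nm.append(0)
                if not missing_nm:
                    logger.info("%s: NM tag absent on some records; treating as 0", path)
                    missing_nm = True
        if max(nm) > max_mismatches:
            skips["mismatch"] += 1
            continue
        if a.reference_name == b.reference_name:
            skips["intra_contig"] += 1
            continue
        end_a, tail_a = _facing_end(a, lengths[a.reference_name])
        end_b, tail_b = _facing_end(b, lengths[b.reference_name])
        links.append(Link(
            library=library.name, priority=library.priority,
            insert_mean=library.insert_mean,
            contig_a=a.reference_name, end_a=end_a, tail_a=tail_a,
            contig_b=b.reference_name, end_b=end_b, tail_b=tail_b,
            read_a=f"{qname}/1", read_b=f"{qname}/2",
        ))
    return links, skips


def _facing_end(rec: pysam.AlignedSegment, contig_len: int) -> tuple[str, int]:
    """Gap-facing contig end and tail for one mate (FR convention)."""
    if rec.is_reverse:
        return LOW, rec.reference_end
    return HIGH, contig_len - rec.reference_start
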