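"""End-to-end convenience wrappers: files in, scaffolds out.

These functions chain the producer modules (map links, SAM links),
bundling, and the greedy scaffolder in the order a command-line user
would, and are what the CLI calls.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional

from . import map_links, sam_links
from .model import LibrarySpec, Link, Scaffold
from .scaffolder import bundle_links, greedy_scaffold

#: Default pseudo mate-pair distance sweep: 5 Mb to 10 Mb in 1 Mb steps,
#: giving 6 map libraries below sequence priority.
DEFAULT_D_START = 5_000_000
DEFAULT_D_END = 10_000_000
DEFAULT_D_STEP = 1_000_000


def sequence_library(name: str, insert_mean: int, priority: int = 1,
                     spread_frac: float = 0.1) -> LibrarySpec:
    """LibrarySpec for a sequencing library, +/- 10% around the nominal
    insert by default."""
    lo = int(round(insert_mean * (1 - spread_frac)))
    hi = int(round(insert_mean * (1 + spread_frac)))
    return LibrarySpec(name, lo, hi, priority)


def map_to_links(map_tsv, psl, contig_lengths: Mapping[str, int],
                 d_start: int = DEFAULT_D_START, d_end: int = DEFAULT_D_END,
                 d_step: int = DEFAULT_D_STEP, priority: int = 2,
                 ) -> tuple[list[Link], list[LibrarySpec], Counter]:
    """Virtual map + marker alignments -> pseudo mate-pair links."""
    markers = map_links.parse_map_table(map_tsv)
    placements = map_links.load_placements(psl)
    libraries = map_links.make_pseudo_libraries(d_start, d_end, d_step, priority)
    pairs = map_links.enumerate_pseudo_pairs(markers, libraries)
    links, skips = map_links.pairs_to_links(pairs, placements, libraries,
                                            contig_lengths)
    return links, libraries, skips


def sam_to_links(sam_paths: Mapping[str, object],
                 libraries: Mapping[str, LibrarySpec],
                 max_mismatches: int = 3) -> tuple[list[Link], Counter]:
    """Paired-end SAM files -> inter-contig links, one library per file."""
    all_links: list[Link] = []
    skips: Counter = Counter()
    for name in sorted(sam_paths):
        links, s = sam_links.parse_sam_pairs(sam_paths[name], libraries[name],
                                             max_mismatches)
        all_links.extend(links)
        skips.update(s)
    return all_links, skips


def scaffold_links(links: Iterable[Link], libraries: Iterable[LibrarySpec],
                   contig_lengths: Mapping[str, int],
                   min_weight_by_priority: Optional[Mapping[int, int]] = None,
                   ) -> tuple[list[Scaffold], list]:
    """Bundle links and run the greedy scaffolder."""
    bundles = bundle_links(links, min_weight_by_priority, libraries)
    return greedy_scaffold(bundles, contig_lengths)
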