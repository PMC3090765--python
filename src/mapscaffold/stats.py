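"""Assembly summary statistics over scaffold spans.

Statistics follow the usual assembly-report conventions: singleton
contigs count as 1-contig scaffolds, spans include estimated gaps, and
N50 is computed over scaffold spans (the span at which the longest
scaffolds accumulate half the total span).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import Scaffold


@dataclass(frozen=True)
class AssemblyStats:
    n_pairs_used: int
    total_span: int
    n50_span: int
    n_scaffolds: int
    pct_contigs_scaffolded: float


def n50(spans: Sequence[int]) -> int:
    """N50 of a list of spans.

    Sort descending; return the span at which the running total first
    reaches half the overall total.
    """
    if not spans:
        raise ValueError("n50 of an empty span list is undefined")
    if min(spans) <= 0:
        raise ValueError("spans must be positive")
    ordered = sorted(spans, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for s in ordered:
        acc += s
        if acc >= half:
            return s
    raise AssertionError("unreachable")


def summarize(scaffolds: Iterable[Scaffold], n_initial_contigs: int,
              n_pairs_used: int = 0) -> AssemblyStats:
    """Tabulate the scaffolding outcome.

    ``pct_contigs_scaffolded`` is the percentage of the initial contigs
    that ended up in a scaffold of >= 2 contigs, to one decimal; the
    scaffold count and N50 include singletons.
    """
    if n_initial_contigs <= 0:
        raise ValueError("n_initial_contigs must be positive")
    scaffolds = list(scaffolds)
    spans = [s.span for s in scaffolds]
    in_multi = sum(s.n_contigs for s in scaffolds if s.n_contigs >= 2)
    return AssemblyStats(
        n_pairs_used=n_pairs_used,
        total_span=sum(spans),
        n50_span=n50(spans),
        n_scaffolds=len(scaffolds),
        pct_contigs_scaffolded=round(100.0 * in_multi / n_initial_contigs, 1),
    )
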