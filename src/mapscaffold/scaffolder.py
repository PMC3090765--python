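"""Greedy priority-aware contig scaffolding from mate-pair links.

Links are first aggregated into *bundles* — all links agreeing on the
same oriented contig-pair join — and bundles are applied greedily in a
total order that puts higher-priority (sequence) evidence before
lower-priority (map) evidence, heavier bundles before lighter ones.
Contig placements are maintained in a union-find structure where every
contig carries an affine transform (offset plus possible reflection)
into its scaffold's frame, so accepting a bundle is a single union and
checking one a transform comparison.  A bundle that contradicts the
placements already accepted — in orientation, or in position beyond its
tolerance — is rejected and counted as a conflict; because sequence
bundles are applied first, map data never overrides sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median_low
from typing import Iterable, Mapping, Optional

from .model import HIGH, LOW, Bundle, ContigPlacement, Link, Scaffold

#: Default minimum bundle weight per priority: sequence joins (priority 1)
#: need two concordant pairs; map joins (priority 2) are scarce enough
#: that a single pseudo pair is accepted.
DEFAULT_MIN_WEIGHT = {1: 2, 2: 1}

MIN_TOLERANCE = 1000


def estimate_gap(link: Link) -> int:
    """Gap implied by one link: insert mean minus both tails.

    Negative values mean the link implies overlapping contigs.
    """
    return link.insert_mean - link.tail_a - link.tail_b


def bundle_links(links: Iterable[Link],
                 min_weight_by_priority: Optional[Mapping[int, int]] = None,
                 libraries: Optional[Iterable] = None) -> list[Bundle]:
    """Aggregate links into weighted oriented contig-pair bundles.

    Links are grouped by (canonical contig pair, facing ends, priority);
    a bundle's gap is the median of its member gaps (low median, so the
    gap is always one actually observed) and its weight the member
    count.  Bundles lighter than the minimum weight for their priority
    are discarded (defaults: priority 1 needs 2 links, others 1).

    ``libraries`` (LibrarySpec iterable) sets each bundle's positional
    tolerance to the largest insert-size spread among its member
    libraries, floored at 1 kb.
    """
    min_w = dict(DEFAULT_MIN_WEIGHT)
    if min_weight_by_priority:
        min_w.update(min_weight_by_priority)
    spread = {l.name: l.insert_spread for l in libraries} if libraries else {}

    groups: dict[tuple, list[Link]] = {}
    for link in links:
        groups.setdefault(_canonical_key(link), []).append(link)

    bundles = []
    for (ca, ea, cb, eb, priority), members in sorted(groups.items()):
        weight = len(members)
        if weight < min_w.get(priority, 1):
            continue
        gaps = sorted(_canonical_gap(l) for l in members)
        tol = max([spread.get(l.library, 0) for l in members] + [MIN_TOLERANCE])
        bundles.append(Bundle(ca, ea, cb, eb, priority, weight,
                              median_low(gaps), tol))
    return bundles


def _canonical_key(link: Link) -> tuple:
    if link.contig_a < link.contig_b:
        return (link.contig_a, link.end_a, link.contig_b, link.end_b, link.priority)
    return (link.contig_b, link.end_b, link.contig_a, link.end_a, link.priority)


def _canonical_gap(link: Link) -> int:
    return estimate_gap(link)  # gap is symmetric under side swap


# ---------------------------------------------------------------------------
# Union-find over 1-D affine transforms (sign s in {+1,-1}, shift t):
# a contig coordinate x maps to scaffold coordinate s*x + t.  A forward
# contig of length L with leftmost base at `start` has (s, t) = (+1, start);
# a reversed one (s, t) = (-1, start + L).

def _compose(s2: int, t2: int, s1: int, t1: int) -> tuple[int, int]:
    """Transform T2 after T1: (T2 . T1)(x) = s2*(s1*x + t1) + t2."""
    return s2 * s1, s2 * t1 + t2


def _invert(s: int, t: int) -> tuple[int, int]:
    return s, -s * t


class _OrientedForest:
    """Union-find where each node stores its transform into its root's frame."""

    def __init__(self) -> None:
        self.parent: dict[str, str] = {}
        self.trans: dict[str, tuple[int, int]] = {}  # node -> (s, t) into parent
        self.size: dict[str, int] = {}

    def add(self, node: str) -> None:
        if node not in self.parent:
            self.parent[node] = node
            self.trans[node] = (1, 0)
            self.size[node] = 1

    def find(self, node: str) -> tuple[str, int, int]:
        """Root and the node's transform into the root frame (path-compressed)."""
        path = []
        cur = node
        while self.parent[cur] != cur:
            path.append(cur)
            cur = self.parent[cur]
        root = cur
        # compress top-down: each node's parent is already attached to root
        # by the time it is processed, so one composition suffices
        for n in reversed(path):
            p = self.parent[n]
            ps, pt = (1, 0) if p == root else self.trans[p]
            self.trans[n] = _compose(ps, pt, *self.trans[n])
            self.parent[n] = root
        if node == root:
            return root, 1, 0
        s, t = self.trans[node]
        return root, s, t

    def union(self, root_small: str, root_big: str, s: int, t: int) -> None:
        """Attach root_small under root_big with transform (s, t)."""
        self.parent[root_small] = root_big
        self.trans[root_small] = (s, t)
        self.size[root_big] += self.size[root_small]


def _implied_transform(bundle: Bundle, len_a: int, len_b: int) -> tuple[int, int]:
    """Transform of contig_b into contig_a's own frame implied by a bundle.

    In a's frame (a spans [0, len_a)), b sits across a gap of
    ``bundle.gap`` off the a-end named by ``end_a``, with b's
    ``end_b``-end facing back toward a.
    """
    g = bundle.gap
    if bundle.end_a == HIGH:
        if bundle.end_b == LOW:   # b forward, starts at len_a + g
            return 1, len_a + g
        return -1, len_a + g + len_b  # b reversed, occupies [len_a+g, ...+len_b)
    if bundle.end_b == LOW:       # b reversed, its base 0 at -g
        return -1, -g
    return 1, -g - len_b          # b forward, high end at -g


def greedy_scaffold(bundles: Iterable[Bundle],
                    contig_lengths: Mapping[str, int]
                    ) -> tuple[list[Scaffold], list[tuple[Bundle, str]]]:
    """Order and orient contigs into scaffolds by greedy bundle application.

    Bundles are processed by (priority ascending, weight descending,
    |gap| ascending, contig pair, ends) — a total order, so output is
    deterministic.  A bundle joining two different scaffolds is always
    accepted and merges them at the implied relative placement; a bundle
    internal to one scaffold is accepted only if the stored placement
    matches the implied one (same relative orientation, offset within
    the bundle's tolerance), otherwise it is rejected as a conflict.

    Every contig in ``contig_lengths`` appears in exactly one output
    scaffold; unlinked contigs become singleton scaffolds.

    Returns ``(scaffolds, conflicts)`` where conflicts pair each
    rejected bundle with a reason (``orientation`` or ``position``).
    """
    forest = _OrientedForest()
    for c in contig_lengths:
        forest.add(c)

    order = sorted(bundles, key=lambda b: (b.priority, -b.weight, abs(b.gap),
                                           b.contig_a, b.contig_b, b.end_a, b.end_b))
    accepted: list[Bundle] = []
    conflicts: list[tuple[Bundle, str]] = []
    for b in order:
        if b.contig_a not in contig_lengths or b.contig_b not in contig_lengths:
            raise KeyError(f"bundle references unknown contig: {b.contig_a}/{b.contig_b}")
        ra, sa, ta = forest.find(b.contig_a)
        rb, sb, tb = forest.find(b.contig_b)
        # b's implied transform into the root-of-a frame
        ms, mt = _compose(sa, ta, *_implied_transform(
            b, contig_lengths[b.contig_a], contig_lengths[b.contig_b]))
        if ra != rb:
            # transform of root_b frame into root_a frame: (implied b->rootA) . (b->rootB)^-1
            us, ut = _compose(ms, mt, *_invert(sb, tb))
            if forest.size[ra] >= forest.size[rb]:
                forest.union(rb, ra, us, ut)
            else:
                forest.union(ra, rb, *_invert(us, ut))
            accepted.append(b)
        else:
            if ms != sb:
                conflicts.append((b, "orientation"))
            elif abs(mt - tb) <= b.tolerance:
                accepted.append(b)
            else:
                conflicts.append((b, "position"))

    scaffolds = _linearize(forest, contig_lengths)
    return scaffolds, conflicts


def _linearize(forest: _OrientedForest,
               contig_lengths: Mapping[str, int]) -> list[Scaffold]:
    """Turn the forest into ordered scaffolds with normalized coordinates.

    Each scaffold is flipped, if needed, so its lexicographically
    smallest contig is forward, then shifted so the leftmost base is 0;
    contigs are sorted by offset (ties by id).  This makes output
    independent of union history.
    """
    members: dict[str, list[tuple[str, int, int]]] = {}
    for c in contig_lengths:
        root, s, t = forest.find(c)
        members.setdefault(root, []).append((c, s, t))

    scaffolds = []
    for group in members.values():
        anchor = min(c for c, _, _ in group)
        flip = next(s for c, s, _ in group if c == anchor) == -1
        placements = []
        for c, s, t in group:
            if flip:
                s, t = -s, -t
            length = contig_lengths[c]
            start = t if s == 1 else t - length
            placements.append((start, c, "+" if s == 1 else "-", length))
        base = min(p[0] for p in placements)
        placements.sort(key=lambda p: (p[0], p[1]))
        scaffolds.append([
            ContigPlacement(c, start - base, orient, length)
            for start, c, orient, length in placements
        ])
    scaffolds.sort(key=lambda ps: ps[0].contig_id)
    return [
        Scaffold(scaffold_id=f"scaffold_{i:05d}", placements=ps)
        for i, ps in enumerate(scaffolds, start=1)
    ]


def verify_layout(scaffolds: Iterable[Scaffold],
                  bundles: Iterable[Bundle]) -> list[Bundle]:
    """Return the bundles NOT satisfied by a final layout.

    A bundle is satisfied when both contigs share a scaffold and the
    stored relative placement matches the bundle's implied one within
    its tolerance.  Used to check self-consistency of accepted bundles.
    """
    where: dict[str, tuple[int, int, int, int]] = {}  # contig -> (scaffold#, s, t, len)
    for i, sc in enumerate(scaffolds):
        for p in sc.placements:
            s = 1 if p.orientation == "+" else -1
            t = p.offset if s == 1 else p.offset + p.length
            where[p.contig_id] = (i, s, t, p.length)
    bad = []
    for b in bundles:
        ia, sa, ta, la = where[b.contig_a]
        ib, sb, tb, lb = where[b.contig_b]
        if ia != ib:
            bad.append(b)
            continue
        ms, mt = _compose(sa, ta, *_implied_transform(b, la, lb))
        if ms != sb or abs(mt - tb) > b.tolerance:
            bad.append(b)
    return bad
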