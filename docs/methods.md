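# Methods

## Problem and model

Low-coverage genome assemblies fragment into contigs far shorter than a
chromosome. Mate-pair (paired-end) reads constrain the distance and
relative orientation of the two contigs their mates land on, but
sequencing libraries cap the bridgeable distance at a few kilobases.
Non-sequence map data — physical (FISH), linkage and synteny maps that
assign markers base-pair positions on chromosomes — carries positional
information at megabase range. This package converts such a *virtual
map* into **pseudo mate-pairs**: every pair of same-chromosome markers
whose map separation falls in a chosen distance bin is treated as the
two reads of a virtual fragment of that insert size. Once each marker
is located on a contig (best BLAT hit), a pseudo pair is an ordinary
mate-pair link and flows through the same scaffolding machinery as
sequence data, just at 5–10 Mb instead of 4–8 kb.

A link between contigs is summarized by which *end* of each contig the
mate faces (`low` = coordinate 0, `high` = coordinate L, under the FR
/ innie convention that mates point toward each other) and a *tail*,
the distance from the mate's outer position to that end. The implied
gap is `insert − tail_a − tail_b`, negative when contigs overlap.

## Pseudo mate-pair libraries

Distance bins are centered on a sweep `d_start … d_end` in `d_step`
increments; bin *d* covers separations `[d − step/2, d + step/2)`, so
bins are disjoint, each marker pair contributes exactly one constraint,
and the mean insert of bin *d* is *d*. The default sweep 5→10 Mb in
1 Mb steps yields six libraries. The 5 Mb floor exists because FISH
only localizes a marker to within a few megabases: at ≥ 4.5 Mb
separation, ±2 Mb positional noise cannot invert a pair's marker order,
so the orientation each pseudo read encodes is trustworthy. Pairs
closer than the lowest bin edge are discarded entirely for the same
reason.

Each pseudo link stores the pair's *actual* map separation as its
insert size rather than the bin mean: it costs nothing and gives
per-pair gap estimates; the bin mean still defines bin membership and
the bundle tolerance (below).

## Sequence links

SAM records are paired by query name. A pair is kept only if both
mates are mapped, each has ≤ 3 mismatches (NM tag; absent ⇒ 0, logged),
and neither is multi-mapping. Multi-mapping is detected as MAPQ 0 on
the primary record or any secondary/supplementary record for that mate
— a mapper-independent proxy for "aligned to multiple locations", since
this toolkit does not run the mapper itself. Same-contig pairs are
tallied but carry no inter-contig information. The nominal insert-size
range of a sequencing library defaults to ±10% around the stated
insert and is user-overridable.

## Bundling and greedy scaffolding

Links grouped by (canonical contig pair, facing ends, priority) form a
*bundle* with weight = link count and gap = low median of member gaps
(always an observed value, robust to outliers). Bundles below a
per-priority weight floor are dropped — defaults: priority 1
(sequence) needs 2 concordant pairs, priority 2 (map) accepts 1,
because pseudo pairs are few but individually reliable at ≥ 5 Mb
separations. A bundle's positional tolerance is the largest insert
spread among its member libraries, floored at 1 kb.

Scaffolding is greedy over bundles sorted by (priority ascending,
weight descending, |gap| ascending, lexicographic pair, ends) — a
total order, so runs are byte-reproducible. Contig placements live in
a union-find forest where each contig carries an affine transform
(sign for orientation, shift for offset) into its scaffold frame;
union-by-size with path compression composes transforms. A bundle
joining two scaffolds always merges them at the implied relative
placement. A bundle internal to one scaffold is accepted only if the
implied placement matches the stored one — same relative orientation,
offset within tolerance — otherwise it is rejected and reported as a
conflict. Because sequence bundles are applied first, a map bundle can
never displace a sequence join regardless of weight: the
sequence-overrides-map priority contract is a direct consequence of
the processing order.

After all bundles, each scaffold is normalized: flipped if needed so
its lexicographically smallest contig reads forward, shifted so the
leftmost base is 0, and contigs sorted by offset. This makes output
independent of union history. Negative estimated gaps are kept on the
in-memory layout; AGP and FASTA emission floor every gap at a 20 bp N
run because AGP coordinates must stay monotone and sequence output
must be syntactically valid.

This is deliberately a simplified scaffolder: a priority-ordered
greedy union with conflict reporting, without repeat detection or
untangling heuristics. Bundles built from link TSVs (CLI `scaffold`
subcommand) use the 1 kb floor tolerance because the TSV does not
carry library spreads; the Python API applies the library-aware rule.

## Statistics

Scaffold *span* is last offset + last contig length, gaps included.
N50 sorts spans descending and returns the span at which the running
total first reaches half the overall total. Singleton contigs count as
1-contig scaffolds in both the scaffold count and the N50 denominator
(the inclusive convention an unscaffolded assembly's report implies);
"% contigs scaffolded" counts contigs in scaffolds of ≥ 2 members over
all initial contigs, to one decimal.

## Simulator

The simulator draws uniform-random A/C/G/T chromosomes, tiles them
into contigs (log-normal lengths parameterised by linear-scale
mean/sd) separated by uniform gaps, assigns each contig a random
emitted orientation, places Poisson-spaced markers, and samples FR
read pairs with Gaussian inserts. Markers get exact single-hit PSL
placements (score = marker length) when they fall wholly inside a
contig; map positions carry uniform ±2 Mb noise (FISH-scale). Reads
are emitted as headered SAM with `NM:i:0`, MAPQ 60, both mates mapped;
reads falling in inter-contig gaps are simply not sampled, mimicking
unassembled sequence. All randomness flows from one seed; identical
configs give byte-identical directories.

Default conditions: 2 × 5 Mb chromosomes, 30 kb mean contigs
(minimum 2 kb), 0.5–3.5 kb gaps, 5 markers/Mb of 500 bp, and 4 kb /
8 kb libraries at 0.25× coverage each (0.5× total, 50 bp reads) —
≈ 310 contigs and ≈ 20 spanning pairs per true adjacency. The
map-rescue scenario uses 2 × 10 Mb chromosomes, 15–25 kb gaps (beyond
any sequence insert) and 10 markers/Mb, so only 5–10 Mb pseudo-pairs
can join contigs. These sizes make every pipeline stage and the
end-to-end recovery property testable in seconds on one CPU.

What the simulator does *not* emulate — and hence what passing tests
do not show about real data: sequencing errors and chimeric pairs
(reads are error-free by construction), repeat-induced mis-mapping
(placements are unique unless the optional `duplicate_segment` flag
plants one repeated region to exercise the multimap filter),
insert-size outliers beyond the Gaussian, map errors other than
positional noise (no translocated or mis-assigned markers), and
assembly errors inside contigs. Real-data precision will be lower than
the simulated 100%.

An optional truth scorer compares predicted against true adjacencies
as orientation-aware canonical pairs (invariant to reading a scaffold
in reverse): precision and recall over adjacency sets, plus a count of
correctly joined but relatively flipped neighbours.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open throughout; PSL is native, map
  positions are 0-based bp.
- PSL best hit uses the BLAT web score
  `matches + repMatches − misMatches − qNumInsert − tNumInsert`; a tie
  across distinct contigs drops the marker (ambiguity creates false
  joins), a tie on one contig keeps the first hit in file order.
- Median gap uses the low median so the stored gap is an observed one.
- Empty inputs: empty marker lists, link lists and SAMs yield empty
  outputs, never errors; an empty span list or zero initial contigs is
  an error (the statistics are undefined).
- All tie-breaks in the bundle order and scaffold normalization are
  lexicographic, leaving no nondeterminism.

## Limitations

Repeats are not detected or untangled; a heavy repeat-induced bundle
that arrives early can seed a wrong merge (merges are never revisited).
Gap estimates inherit map-position noise at megabase scale, so
map-derived gaps are indicative only. Bambus-format export is
best-effort interop validated by round-trip parsing, not against the
original binary; BAM/CRAM input is out of scope (SAM only).
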