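# mapscaffold

Scaffold a fragmented genome assembly with **non-sequence map data** —
physical (FISH), linkage and synteny marker maps — alongside ordinary
paired-end sequencing libraries.

Low-coverage assemblies break into contigs that short-insert mate
pairs (4–8 kb) cannot stitch across large gaps or long repeats. A
*virtual genome map* assigns markers base-pair positions on
chromosomes at megabase range. `mapscaffold` turns every
same-chromosome marker pair a set distance apart into a **pseudo
mate-pair** — the two markers act as the reads of a virtual fragment
of that insert size — and feeds those constraints, together with
sequence-based links, to a priority-aware greedy scaffolder in which
**sequence data overrides map data** whenever the two conflict.

The core objects: a link between contigs `a` and `b` records which
gap-facing end of each contig the mate points at and its *tail*
(distance from the mate to that end), so the implied inter-contig gap
is `insert − tail_a − tail_b`. Links agreeing on the same oriented
join are merged into a bundle of weight *w* and median gap *g*;
bundles are applied greedily by (priority, −w, |g|) over a union-find
of oriented contig placements, and inconsistent bundles are rejected
as conflicts. Scaffold quality is reported as total span, N50 span
(the span at which the longest scaffolds reach half the total),
scaffold count, and % of contigs placed in multi-contig scaffolds.

Pseudo libraries default to a 5→10 Mb sweep in 1 Mb bins (six
libraries). The 5 Mb floor keeps marker order trustworthy despite the
few-megabase imprecision of FISH localization.

## Worked example

The built-in simulator generates a complete seeded fixture — contig
FASTA, virtual-map TSV, marker PSL, per-library SAM, and the true
layout — so the whole pipeline runs without external data. Here the
true gaps (15–25 kb) exceed every sequence insert, the regime where
map data rescues the assembly:

```sh
mapscaffold simulate --seed 7 --out fix --n-chromosomes 2 \
    --chromosome-length 10000000 --gap-min 15000 --gap-max 25000
# fixture in fix: 402 contigs, 400 true adjacencies

mapscaffold map2links --map fix/map.tsv --psl fix/markers.psl \
    --contigs fix/contigs.fa --out map.links.tsv
# 161 links
# skipped unplaced: 316

mapscaffold sam2links --sam fix/reads_pe4k.sam --library-name pe4k \
    --insert-min 3600 --insert-max 4400 --out pe4k.links.tsv
# 0 links
# skipped intra_contig: 26231

mapscaffold scaffold --links pe4k.links.tsv --links map.links.tsv \
    --contigs fix/contigs.fa --out-prefix asm
# 361 scaffolds, 62 conflicts

mapscaffold stats --agp asm.agp --contigs fix/contigs.fa
# n_pairs_used  total_span  n50_span  n_scaffolds  pct_contigs_scaffolded
# 0             24169196    6664218   361          10.7
```

Reading the numbers: the 4 kb library yields **zero** inter-contig
links — every one of its 26,231 pairs lands inside a single contig,
because no 4 kb fragment can span a 15–25 kb gap. The map contributes
161 pseudo mate-pair links (316 pairs skipped because a marker fell in
an unassembled gap and has no contig placement). Those map links alone
lift the N50 from contig scale (~33 kb) to 6.66 Mb and reduce 402
contigs to 361 scaffolds; only 10.7% of contigs join a scaffold, yet
the assembly's large-scale structure is recovered — map data adds few
joins but very long-range ones. `asm.conflicts.tsv` lists the 62
rejected bundles; `export-bambus` writes legacy Bambus mates files
from any link TSV.

The same pipeline is scriptable from Python (`mapscaffold.pipeline`),
and `mapscaffold.simulator.score_against_truth` grades any result
against the simulated truth.

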