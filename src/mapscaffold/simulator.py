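"""Synthetic fixtures with known ground truth for the whole pipeline.

The simulator draws a random genome, tiles each chromosome into contigs
separated by unassembled gaps, places markers along the chromosomes
with FISH-scale positional noise, and samples FR read pairs from each
insert library.  It writes exactly the files the pipeline consumes —
contig FASTA, virtual-map TSV, marker PSL, per-library SAM — plus the
true layout (AGP and an adjacency table), so scaffolding output can be
scored against truth.

The defaults emulate the study conditions this toolkit targets: a
fragmented low-coverage assembly (contigs a few tens of kb), a sparse
marker map whose positions are only trustworthy to a couple of
megabases, and ~0.5x of 4 kb / 8 kb paired-end data.  Reads are
error-free and uniquely placed by construction; an optional duplicated
segment plants multi-mapping reads to exercise that filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import write_agp
from .model import ContigPlacement, Scaffold

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadLibraryConfig:
    """One paired-end library: FR pairs with Gaussian insert sizes."""

    name: str
    insert_mean: int
    insert_sd: int
    read_len: int = 50
    coverage: float = 0.25  # sequence coverage contributed by this library


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    contig_len_mean: int = 30_000    # linear-scale mean of the log-normal
    contig_len_sd: int = 15_000
    contig_len_min: int = 2_000
    gap_min: int = 500
    gap_max: int = 3_500
    marker_density_per_mb: float = 5.0
    marker_length: int = 500
    map_noise: int = 2_000_000       # uniform +/- bp added to marker map positions
    libraries: tuple[ReadLibraryConfig, ...] = (
        ReadLibraryConfig("pe4k", 4_000, 400),
        ReadLibraryConfig("pe8k", 8_000, 800),
    )
    duplicate_segment: bool = False
    duplicate_segment_len: int = 5_000

    def __post_init__(self) -> None:
        if self.contig_len_mean >= self.chromosome_length:
            raise ValueError("contig mean length must be below chromosome length")
        for name, val in (("chromosome_length", self.chromosome_length),
                          ("contig_len_mean", self.contig_len_mean),
                          ("contig_len_min", self.contig_len_min),
                          ("gap_min", self.gap_min), ("gap_max", self.gap_max),
                          ("marker_length", self.marker_length)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TruthContig:
    contig_id: str
    chromosome: str
    start: int        # true leftmost bp on the chromosome
    length: int
    orientation: str  # '+' if emitted forward, '-' if reverse-complemented


@dataclass(frozen=True)
class TruthAdjacency:
    contig_a: str
    orient_a: str
    contig_b: str
    orient_b: str
    gap: int


@dataclass
class TruthLayout:
    """Ground-truth contig layout: tiling plus ordered adjacencies."""

    contigs: dict[str, TruthContig]
    adjacencies: list[TruthAdjacency]

    def as_scaffolds(self) -> list[Scaffold]:
        """The true layout expressed as one scaffold per chromosome."""
        by_chrom: dict[str, list[TruthContig]] = {}
        for tc in self.contigs.values():
            by_chrom.setdefault(tc.chromosome, []).append(tc)
        out = []
        for chrom in sorted(by_chrom):
            tcs = sorted(by_chrom[chrom], key=lambda t: t.start)
            base = tcs[0].start
            out.append(Scaffold(
                scaffold_id=chrom,
                placements=[ContigPlacement(t.contig_id, t.start - base,
                                            t.orientation, t.length)
                            for t in tcs]))
        return out


@dataclass
class SimFixture:
    """Paths to the generated files plus the in-memory truth."""

    out_dir: Path
    contigs_fasta: Path
    map_tsv: Path
    marker_psl: Path
    sam_paths: dict[str, Path]
    truth_agp: Path
    truth_tsv: Path
    truth: TruthLayout
    config: SimConfig


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def simulate_fixture(config: SimConfig, out_dir) -> SimFixture:
    """Generate the complete fixture into ``out_dir``.

    All randomness derives from ``config.seed``; the same config writes
    byte-identical files every time.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genomes = {c: _random_genome(rng, config.chromosome_length) for c in chrom_names}

    truth = _tile_contigs(rng, config, chrom_names)
    dup_regions = _plant_duplicate(rng, config, genomes, truth)
    contig_seqs = _contig_sequences(genomes, truth)

    contigs_fasta = out / "contigs.fa"
    _write_fasta(contig_seqs, contigs_fasta)

    map_tsv = out / "map.tsv"
    marker_psl = out / "markers.psl"
    _simulate_markers(rng, config, chrom_names, truth, map_tsv, marker_psl)

    sam_paths = {}
    for lib in config.libraries:
        sam_path = out / f"reads_{lib.name}.sam"
        _simulate_reads(rng, config, lib, chrom_names, truth, contig_seqs,
                        dup_regions, sam_path)
        sam_paths[lib.name] = sam_path

    truth_agp = out / "truth.agp"
    write_agp(truth.as_scaffolds(), truth_agp)
    truth_tsv = out / "truth_adjacencies.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("contig_a\torient_a\tcontig_b\torient_b\tgap\n")
        for adj in truth.adjacencies:
            fh.write(f"{adj.contig_a}\t{adj.orient_a}\t{adj.contig_b}\t"
                     f"{adj.orient_b}\t{adj.gap}\n")

    return SimFixture(out, contigs_fasta, map_tsv, marker_psl, sam_paths,
                      truth_agp, truth_tsv, truth, config)


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _tile_contigs(rng: np.random.Generator, config: SimConfig,
                  chrom_names: Sequence[str]) -> TruthLayout:
    # log-normal parameterised by its linear-scale mean/sd
    cv2 = (config.contig_len_sd / config.contig_len_mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(config.contig_len_mean) - sigma ** 2 / 2

    contigs: dict[str, TruthContig] = {}
    adjacencies: list[TruthAdjacency] = []
    k = 0
    for chrom in chrom_names:
        pos = 0
        prev: Optional[TruthContig] = None
        while pos + config.contig_len_min <= config.chromosome_length:
            clen = int(rng.lognormal(mu, sigma))
            clen = max(clen, config.contig_len_min)
            clen = min(clen, config.chromosome_length - pos)
            if clen < config.contig_len_min:
                break
            orient = "+" if rng.random() < 0.5 else "-"
            k += 1
            tc = TruthContig(f"ctg{k:05d}", chrom, pos, clen, orient)
            contigs[tc.contig_id] = tc
            if prev is not None:
                adjacencies.append(TruthAdjacency(
                    prev.contig_id, prev.orientation,
                    tc.contig_id, tc.orientation,
                    pos - (prev.start + prev.length)))
            prev = tc
            pos += clen + int(rng.integers(config.gap_min, config.gap_max + 1))
    return TruthLayout(contigs, adjacencies)


def _plant_duplicate(rng: np.random.Generator, config: SimConfig,
                     genomes: dict[str, str],
                     truth: TruthLayout) -> list[tuple[str, int, int]]:
    """Optionally copy one intra-contig segment elsewhere, returning the
    genome regions (chrom, start, end) whose reads multi-map."""
    if not config.duplicate_segment:
        return []
    seglen = config.duplicate_segment_len
    hosts = [tc for tc in truth.contigs.values() if tc.length >= 3 * seglen]
    if len(hosts) < 2:
        raise ValueError("no contigs long enough to host a duplicate segment")
    idx = rng.choice(len(hosts), size=2, replace=False)
    src, dst = hosts[int(idx[0])], hosts[int(idx[1])]
    s_off = int(rng.integers(seglen, src.length - 2 * seglen))
    d_off = int(rng.integers(seglen, dst.length - 2 * seglen))
    seg = genomes[src.chromosome][src.start + s_off: src.start + s_off + seglen]
    g = genomes[dst.chromosome]
    genomes[dst.chromosome] = (g[: dst.start + d_off] + seg
                               + g[dst.start + d_off + seglen:])
    return [(src.chromosome, src.start + s_off, src.start + s_off + seglen),
            (dst.chromosome, dst.start + d_off, dst.start + d_off + seglen)]


def _contig_sequences(genomes: Mapping[str, str],
                      truth: TruthLayout) -> dict[str, str]:
    seqs = {}
    for tc in truth.contigs.values():
        s = genomes[tc.chromosome][tc.start: tc.start + tc.length]
        seqs[tc.contig_id] = s if tc.orientation == "+" else _revcomp(s)
    return seqs


def _write_fasta(seqs: Mapping[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _simulate_markers(rng: np.random.Generator, config: SimConfig,
                      chrom_names: Sequence[str], truth: TruthLayout,
                      map_tsv: Path, marker_psl: Path) -> None:
    sources = np.array(["FISH", "linkage", "synteny"])
    by_chrom: dict[str, list[TruthContig]] = {}
    for tc in truth.contigs.values():
        by_chrom.setdefault(tc.chromosome, []).append(tc)

    map_rows = []
    psl_rows = []
    k = 0
    mlen = config.marker_length
    for chrom in chrom_names:
        tcs = sorted(by_chrom.get(chrom, []), key=lambda t: t.start)
        starts = np.array([t.start for t in tcs])
        n = rng.poisson(config.marker_density_per_mb
                        * config.chromosome_length / 1e6)
        positions = np.sort(rng.integers(0, config.chromosome_length - mlen,
                                         size=n))
        noise = rng.integers(-config.map_noise, config.map_noise + 1, size=n)
        src = sources[rng.integers(0, len(sources), size=n)]
        for i in range(n):
            k += 1
            p = int(positions[i])
            map_pos = int(np.clip(p + noise[i], 0, config.chromosome_length - 1))
            mid = f"mk{k:05d}"
            map_rows.append((mid, chrom, map_pos, f"gene_{k}", src[i]))
            # exact placement if the marker lies wholly inside one contig
            j = int(np.searchsorted(starts, p, side="right")) - 1
            if j < 0:
                continue
            tc = tcs[j]
            if p + mlen > tc.start + tc.length:
                continue
            if tc.orientation == "+":
                t_start, strand = p - tc.start, "+"
            else:
                t_start, strand = tc.start + tc.length - (p + mlen), "-"
            psl_rows.append((mlen, 0, 0, 0, 0, 0, 0, 0, strand, mid, mlen, 0,
                             mlen, tc.contig_id, tc.length, t_start,
                             t_start + mlen, 1, f"{mlen},", "0,", f"{t_start},"))

    with open(map_tsv, "w") as fh:
        fh.write("marker_id\tchromosome\tmap_pos\tgene_name\tsource\n")
        for row in map_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(marker_psl, "w") as fh:
        for row in psl_rows:
            fh.write("\t".join(map(str, row)) + "\n")


def _simulate_reads(rng: np.random.Generator, config: SimConfig,
                    lib: ReadLibraryConfig, chrom_names: Sequence[str],
                    truth: TruthLayout, contig_seqs: Mapping[str, str],
                    dup_regions: list[tuple[str, int, int]],
                    sam_path: Path) -> None:
    rl = lib.read_len
    by_chrom: dict[str, list[TruthContig]] = {}
    for tc in truth.contigs.values():
        by_chrom.setdefault(tc.chromosome, []).append(tc)

    records: list[str] = []
    for chrom in chrom_names:
        tcs = sorted(by_chrom.get(chrom, []), key=lambda t: t.start)
        starts = np.array([t.start for t in tcs])
        ends = np.array([t.start + t.length for t in tcs])
        L = config.chromosome_length
        n_pairs = int(lib.coverage * L / (2 * rl))
        inserts = np.maximum(np.rint(rng.normal(lib.insert_mean, lib.insert_sd,
                                                size=n_pairs)).astype(np.int64),
                             2 * rl + 1)
        inserts = np.minimum(inserts, L - 1)
        frag_starts = rng.integers(0, L - inserts)
        r1s, r1e = frag_starts, frag_starts + rl
        r2e = frag_starts + inserts
        r2s = r2e - rl
        # containing contig of each read, or -1 if it straddles a gap
        i1 = np.searchsorted(starts, r1s, side="right") - 1
        i2 = np.searchsorted(starts, r2s, side="right") - 1
        ok = (i1 >= 0) & (i2 >= 0)
        ok &= np.where(i1 >= 0, r1e <= ends[np.clip(i1, 0, None)], False)
        ok &= np.where(i2 >= 0, r2e <= ends[np.clip(i2, 0, None)], False)
        for p in np.flatnonzero(ok):
            tc1, tc2 = tcs[int(i1[p])], tcs[int(i2[p])]
            qname = f"{lib.name}_{chrom}_{int(p):06d}"
            rec1 = _sam_mate(qname, True, tc1, int(r1s[p]), int(r1e[p]), "+",
                             contig_seqs, rl)
            rec2 = _sam_mate(qname, False, tc2, int(r2s[p]), int(r2e[p]), "-",
                             contig_seqs, rl)
            records.extend(_pair_records(rec1, rec2, chrom, dup_regions,
                                         (int(r1s[p]), int(r1e[p])),
                                         (int(r2s[p]), int(r2e[p]))))

    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid in sorted(contig_seqs):
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(contig_seqs[cid])}\n")
        for rec in records:
            fh.write(rec + "\n")


def _sam_mate(qname: str, first: bool, tc: TruthContig, g_start: int,
              g_end: int, genome_strand: str, contig_seqs: Mapping[str, str],
              rl: int) -> dict:
    if tc.orientation == "+":
        pos = g_start - tc.start
        strand = genome_strand
    else:
        pos = tc.start + tc.length - g_end
        strand = "-" if genome_strand == "+" else "+"
    seq = contig_seqs[tc.contig_id][pos: pos + rl]
    return {"qname": qname, "first": first, "contig": tc.contig_id,
            "pos": pos, "strand": strand, "seq": seq}


def _pair_records(a: dict, b: dict, chrom: str,
                  dup_regions: list[tuple[str, int, int]],
                  g1: tuple[int, int], g2: tuple[int, int]) -> list[str]:
    out = []
    for rec, mate, g in ((a, b, g1), (b, a, g2)):
        flag = 0x1 | (0x40 if rec["first"] else 0x80)
        if rec["strand"] == "-":
            flag |= 0x10
        if mate["strand"] == "-":
            flag |= 0x20
        in_dup = any(c == chrom and s <= g[0] and g[1] <= e
                     for c, s, e in dup_regions)
        mapq = 0 if in_dup else 60
        rnext = "=" if mate["contig"] == rec["contig"] else mate["contig"]
        rl = len(rec["seq"])
        out.append("\t".join(map(str, (
            rec["qname"], flag, rec["contig"], rec["pos"] + 1, mapq,
            f"{rl}M", rnext, mate["pos"] + 1, 0, rec["seq"], "I" * rl,
            "NM:i:0"))))
        if in_dup:
            # secondary record at the other copy of the duplicated segment
            other = next((c, s, e) for c, s, e in dup_regions
                         if not (c == chrom and s <= g[0] and g[1] <= e))
            out.append("\t".join(map(str, (
                rec["qname"], flag | 0x100, rec["contig"], rec["pos"] + 1, 0,
                f"{rl}M", rnext, mate["pos"] + 1, 0, "*", "*", "NM:i:0"))))
    return out


def score_against_truth(scaffolds: Iterable[Scaffold],
                        truth: TruthLayout) -> dict[str, float]:
    """Score a scaffolding result against the true layout.

    Adjacencies (consecutive oriented contig pairs) are compared as
    orientation-aware canonical pairs, invariant to reading a scaffold
    in reverse.  Returns adjacency ``precision`` and ``recall`` plus
    ``orientation_errors`` — correctly joined neighbours whose relative
    orientation is flipped.
    """
    truth_canon = {_canon_adj(a.contig_a, a.orient_a, a.contig_b, a.orient_b)
                   for a in truth.adjacencies}
    truth_pairs = {frozenset((a.contig_a, a.contig_b)):
                   (a.orient_a == a.orient_b) for a in truth.adjacencies}

    predicted = set()
    for sc in scaffolds:
        for p, q in zip(sc.placements, sc.placements[1:]):
            for c in (p, q):
                if c.contig_id not in truth.contigs:
                    raise ValueError(f"unknown contig id {c.contig_id!r}")
            predicted.add(_canon_adj(p.contig_id, p.orientation,
                                     q.contig_id, q.orientation))

    correct = predicted & truth_canon
    orientation_errors = 0
    for (ca, oa, cb, ob) in predicted - truth_canon:
        key = frozenset((ca, cb))
        if key in truth_pairs and (oa == ob) != truth_pairs[key]:
            orientation_errors += 1

    precision = len(correct) / len(predicted) if predicted else 1.0
    recall = len(correct) / len(truth_canon) if truth_canon else 1.0
    return {"precision": precision, "recall": recall,
            "orientation_errors": orientation_errors,
            "n_predicted": len(predicted), "n_truth": len(truth_canon)}


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def _canon_adj(ca: str, oa: str, cb: str, ob: str) -> tuple[str, str, str, str]:
    fwd = (ca, oa, cb, ob)
    rev = (cb, _flip(ob), ca, _flip(oa))
    return min(fwd, rev)
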