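"""File I/O: contig lengths, link tables, AGP layouts, scaffold FASTA."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .model import Bundle, ContigPlacement, Link, Scaffold

#: Minimum run of N's written for a gap in scaffold sequence/AGP output;
#: estimated gaps can be negative (overlapping contigs) but emitted
#: coordinates must stay monotone.
MIN_GAP_N = 20

LINK_COLUMNS = ["library", "priority", "insert_mean",
                "contig_a", "end_a", "tail_a",
                "contig_b", "end_b", "tail_b",
                "read_a", "read_b"]


def read_contig_lengths(path) -> dict[str, int]:
    """Contig lengths from a FASTA file or a 2-column TSV (id, length)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["contig_id", "length"], dtype={0: str, 1: int})
    return dict(zip(df["contig_id"], df["length"]))


def read_contig_sequences(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_links_tsv(links: Iterable[Link], path) -> None:
    rows = [[l.library, l.priority, l.insert_mean,
             l.contig_a, l.end_a, l.tail_a,
             l.contig_b, l.end_b, l.tail_b,
             l.read_a, l.read_b] for l in links]
    pd.DataFrame(rows, columns=LINK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_links_tsv(path) -> list[Link]:
    df = pd.read_csv(path, sep="\t", dtype={"read_a": str, "read_b": str},
                     keep_default_na=False)
    return [Link(library=r.library, priority=int(r.priority),
                 insert_mean=int(r.insert_mean),
                 contig_a=str(r.contig_a), end_a=r.end_a, tail_a=int(r.tail_a),
                 contig_b=str(r.contig_b), end_b=r.end_b, tail_b=int(r.tail_b),
                 read_a=r.read_a, read_b=r.read_b)
            for r in df.itertuples(index=False)]


def write_agp(scaffolds: Iterable[Scaffold], path) -> None:
    """Write an AGP v2.0 layout, one object per scaffold.

    Gap lines use type ``scaffold``/``paired-ends``; a negative or
    sub-20 bp estimated gap is floored at 20 bp so object coordinates
    stay monotone (the unfloored estimate lives in the Scaffold object).
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for sc in scaffolds:
            pos = 1
            part = 1
            prev: ContigPlacement | None = None
            for p in sc.placements:
                if prev is not None:
                    gap = p.offset - (prev.offset + prev.length)
                    gap = max(gap, MIN_GAP_N)
                    fh.write(f"{sc.scaffold_id}\t{pos}\t{pos + gap - 1}\t{part}\t"
                             f"N\t{gap}\tscaffold\tyes\tpaired-ends\n")
                    pos += gap
                    part += 1
                fh.write(f"{sc.scaffold_id}\t{pos}\t{pos + p.length - 1}\t{part}\t"
                         f"W\t{p.contig_id}\t1\t{p.length}\t{p.orientation}\n")
                pos += p.length
                part += 1
                prev = p


def read_agp(path) -> list[Scaffold]:
    """Read scaffold layouts back from an AGP v2.0 file (W and N lines)."""
    scaffolds: dict[str, list[ContigPlacement]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            obj, start, comp_type = f[0], int(f[1]), f[4]
            if comp_type in ("N", "U"):
                continue
            if obj not in scaffolds:
                scaffolds[obj] = []
                order.append(obj)
            length = int(f[7]) - int(f[6]) + 1
            scaffolds[obj].append(
                ContigPlacement(f[5], start - 1, f[8], length))
    return [Scaffold(scaffold_id=o, placements=scaffolds[o]) for o in order]


_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_scaffold_fasta(scaffolds: Iterable[Scaffold],
                         contig_seqs: Mapping[str, str], path,
                         width: int = 80) -> None:
    """Emit scaffold sequences with gaps as N runs (minimum 20)."""
    with open(path, "w") as fh:
        for sc in scaffolds:
            parts = []
            prev = None
            for p in sc.placements:
                if prev is not None:
                    gap = max(p.offset - (prev.offset + prev.length), MIN_GAP_N)
                    parts.append("N" * gap)
                seq = contig_seqs[p.contig_id]
                parts.append(seq if p.orientation == "+" else revcomp(seq))
                prev = p
            seq = "".join(parts)
            fh.write(f">{sc.scaffold_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_conflict_report(conflicts: Iterable[tuple[Bundle, str]], path) -> None:
    rows = [[b.contig_a, b.end_a, b.contig_b, b.end_b,
             b.priority, b.weight, b.gap, reason]
            for b, reason in conflicts]
    pd.DataFrame(rows, columns=["contig_a", "end_a", "contig_b", "end_b",
                                "priority", "weight", "gap", "reason"]
                 ).to_csv(path, sep="\t", index=False)
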