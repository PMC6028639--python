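"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA/FASTQ (via Biopython), BED6/BED12, Bismark-style coverage TSV, and the
design/ground-truth tables. Coordinates are 0-based half-open in memory;
coverage files use the 1-based inclusive Bismark dialect."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import ExperimentalUnit, GeneModel, Reference


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(contigs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path) -> None:
    """reads: iterable of (id, bases, qual-string)."""
    with _open_text(path, "wt") as fh:
        for rid, bases, qual in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{qual}\n")


def read_fastq(path):
    """Yield (id, bases, qual-string); fast tuple-based parser."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_bed6(df: pd.DataFrame, path) -> None:
    """Columns contig, start, end, name, score, strand (missing ones filled)."""
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out:
            out[col] = default
    out[["contig", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path) -> pd.DataFrame:
    names = ["contig", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_tags_bed(tags: pd.DataFrame, path) -> None:
    """Single-position tag track as BED3 (end = pos + 1)."""
    out = pd.DataFrame(
        {"contig": tags["contig"], "start": tags["pos"], "end": tags["pos"] + 1}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tags_bed(path) -> pd.DataFrame:
    df = read_bed6(path)
    return pd.DataFrame({"contig": df["contig"], "pos": df["start"]})


def write_genes_bed12(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
        rows.append(
            (g.contig, g.start, g.end, g.name, 0, g.strand,
             g.start, g.end, "0,0,0", len(g.exons), sizes, starts)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None)
    genes = []
    for row in df.itertuples(index=False):
        contig, start, end, name, _score, strand = row[0], int(row[1]), int(row[2]), row[3], row[4], row[5]
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        genes.append(GeneModel(contig, start, end, strand, name, exons))
    return genes


def write_coverage(counts: pd.DataFrame, path) -> None:
    """Bismark-style coverage TSV: contig, start(1-based), end(=start),
    methylation %, count_methylated, count_unmethylated.

    ``counts`` has columns contig, pos (0-based), n_meth, n_unmeth.
    """
    depth = counts["n_meth"] + counts["n_unmeth"]
    out = pd.DataFrame(
        {
            "contig": counts["contig"],
            "start": counts["pos"] + 1,
            "end": counts["pos"] + 1,
            "percent": 100.0 * counts["n_meth"] / depth,
            "n_meth": counts["n_meth"],
            "n_unmeth": counts["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_coverage(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "percent", "n_meth", "n_unmeth"],
    )
    return pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["start"] - 1,
            "n_meth": df["n_meth"].astype(int),
            "n_unmeth": df["n_unmeth"].astype(int),
        }
    )


def write_design(units: list[ExperimentalUnit], path) -> None:
    from .simulate import design_frame

    design_frame(units).to_csv(path, sep="\t")


def read_design(path) -> list[ExperimentalUnit]:
    df = pd.read_csv(path, sep="\t", index_col="unit_id")
    return [
        ExperimentalUnit(uid, r["group"], r["diet"], r["sex"], int(r["n_animals"]))
        for uid, r in df.iterrows()
    ]


def write_islands_bed(islands: list[tuple[str, int, int]], path) -> None:
    df = pd.DataFrame(islands, columns=["contig", "start", "end"])
    df["name"] = [f"island_{i + 1}" for i in range(len(df))]
    write_bed6(df, path)


def read_islands_bed(path) -> list[tuple[str, int, int]]:
    df = read_bed6(path)
    return [(r.contig, int(r.start), int(r.end)) for r in df.itertuples()]
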