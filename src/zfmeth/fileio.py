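"""Readers and writers for the standard text formats the pipeline touches.

Conventions enforced at the boundary: BED is 0-based half-open, GFF3 is
1-based inclusive, cytosine reports are 1-based; everything in memory is
0-based half-open.  Malformed lines raise :class:`ParseError` carrying the
file, line number and offending field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CountMatrix, GenomicInterval
from .expression import Gene

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_count_matrix",
    "write_count_matrix",
    "read_bedgraph",
    "write_bedgraph",
]

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "count_m", "count_u"]


class ParseError(ValueError):
    def __init__(self, path, line_no: int, field: str, message: str):
        super().__init__(f"{path}:{line_no}: field {field!r}: {message}")
        self.path, self.line_no, self.field = str(path), line_no, field


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _int_field(value: str, path, line_no: int, field: str, minimum: int = 0) -> int:
    try:
        v = int(value)
    except ValueError:
        raise ParseError(path, line_no, field, f"not an integer: {value!r}")
    if v < minimum:
        raise ParseError(path, line_no, field, f"must be >= {minimum}, got {v}")
    return v


def read_bed(path) -> list[GenomicInterval]:
    """BED (3-6 columns) -> intervals; 0-based half-open, as the format."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(path, line_no, "line", "fewer than 3 columns")
            chrom = fields[0]
            start = _int_field(fields[1], path, line_no, "start")
            end = _int_field(fields[2], path, line_no, "end")
            if end <= start:
                raise ParseError(path, line_no, "end", f"end {end} <= start {start}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            out.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """BED6: chrom, start, end, name, score(0), strand."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                f"{iv.strand or '.'}\n"
            )


def read_gff3(path) -> list[Gene]:
    """Gene features of a GFF3 file (1-based inclusive -> half-open).

    Reads ``gene`` lines; ``ID`` from the attribute column, exon length
    from an ``exon_length`` attribute when present, else the gene span.
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, line_no, "line", "expected 9 columns")
            if fields[2] != "gene":
                continue
            chrom = fields[0]
            start1 = _int_field(fields[3], path, line_no, "start", minimum=1)
            end1 = _int_field(fields[4], path, line_no, "end", minimum=1)
            if end1 < start1:
                raise ParseError(path, line_no, "end", "end before start")
            strand = fields[6]
            if strand not in "+-":
                raise ParseError(path, line_no, "strand", f"invalid: {strand!r}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if not gene_id:
                raise ParseError(path, line_no, "attributes", "missing ID")
            exon_length = int(attrs.get("exon_length", end1 - start1 + 1))
            genes.append(
                Gene(
                    gene_id,
                    GenomicInterval(chrom, start1 - 1, end1, strand=strand),
                    exon_length=exon_length,
                )
            )
    return genes


def write_gff3(genes: Sequence[Gene], path, source: str = "zfmeth") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};exon_length={g.exon_length}\n"
            )


def read_cytosine_report(path) -> pd.DataFrame:
    """Cytosine report TSV: chrom, pos (1-based), strand, context, #C, #T."""
    df = pd.read_csv(
        path, sep="\t",
        names=CYTOSINE_COLUMNS, header=0,
        dtype={"chrom": str, "strand": str, "context": str},
    )
    for line_offset, row in enumerate(df.itertuples(index=False)):
        line_no = line_offset + 2  # header is line 1
        if row.strand not in "+-":
            raise ParseError(path, line_no, "strand", f"invalid: {row.strand!r}")
        if row.context not in ("CG", "CHG", "CHH"):
            raise ParseError(path, line_no, "context", f"invalid: {row.context!r}")
        if row.pos < 1:
            raise ParseError(path, line_no, "pos", "positions are 1-based")
        if row.count_m < 0 or row.count_u < 0:
            raise ParseError(path, line_no, "counts", "negative count")
    df["pos"] = df["pos"].astype(np.int64)
    df["count_m"] = df["count_m"].astype(np.int64)
    df["count_u"] = df["count_u"].astype(np.int64)
    return df


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, columns=CYTOSINE_COLUMNS)


def read_count_matrix(path, groups_path=None) -> CountMatrix | pd.DataFrame:
    """Count TSV (header = sample IDs, index = feature IDs).

    With ``groups_path`` (two-column sample/group TSV) returns a
    CountMatrix, else the bare DataFrame.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ParseError(path, 0, "counts", "negative count present")
    if groups_path is None:
        return df
    gdf = pd.read_csv(groups_path, sep="\t", names=["sample", "group"], header=0)
    return CountMatrix(df, dict(zip(gdf["sample"], gdf["group"])))


def write_count_matrix(
    counts: CountMatrix | pd.DataFrame, path, groups_path=None
) -> None:
    if isinstance(counts, CountMatrix):
        counts.counts.to_csv(path, sep="\t")
        if groups_path is not None:
            pd.DataFrame(
                {"sample": list(counts.groups), "group": list(counts.groups.values())}
            ).to_csv(groups_path, sep="\t", index=False)
    else:
        counts.to_csv(path, sep="\t")


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """bedGraph -> per-bp float arrays (unset positions are 0)."""
    track = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(path, line_no, "line", "expected 4 columns")
            chrom = fields[0]
            if chrom not in track:
                raise ParseError(path, line_no, "chrom", f"unknown: {chrom!r}")
            start = _int_field(fields[1], path, line_no, "start")
            end = _int_field(fields[2], path, line_no, "end")
            try:
                value = float(fields[3])
            except ValueError:
                raise ParseError(path, line_no, "value", f"not a number: {fields[3]!r}")
            track[chrom][start:end] = value
    return track


def write_bedgraph(track: Mapping[str, np.ndarray], path) -> None:
    """Per-bp arrays -> run-length-compressed bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom, arr in track.items():
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


# ---------------------------------------------------------------------------
# Simulated dataset round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset, outdir) -> None:
    """Write every component of a simulated dataset as plain text."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = dataset.genome
    write_fasta(g.genome, out / "genome.fa")
    write_bed(g.sites, out / "sites.bed")
    write_bed([x.interval for x in g.genes], out / "genes.bed")
    write_gff3(g.genes, out / "genes.gff3")
    write_bed(g.trna, out / "trna.bed")
    g.truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    g.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    for ab, df in dataset.chip.items():
        df.to_csv(out / f"chip_{ab}.tsv", sep="\t")
    for group, tab in dataset.bisulfite.items():
        write_cytosine_report(tab, out / f"cytosine_report_{group}.tsv")
    for channel, cm in dataset.sirna.counts.items():
        write_count_matrix(
            cm, out / f"sirna_{channel}.tsv", out / f"sirna_{channel}.groups.tsv"
        )
    write_count_matrix(
        dataset.expression, out / "expression.tsv", out / "expression.groups.tsv"
    )
    dataset.exon_lengths.rename("exon_length").to_csv(out / "exon_lengths.tsv", sep="\t")
    dataset.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
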