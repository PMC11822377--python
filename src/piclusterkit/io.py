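"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; the tabular formats (BED6 annotation with a
``name|class[|histone]`` name field, narrowPeak, bedGraph, TSV tables) go
through pandas.  All writers emit deterministic (chrom, start) ordering so
identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneAnnotation

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "summit",
]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = []
    for g in genes:
        name = f"{g.name}|{g.gene_class}" + ("|histone" if g.histone else "")
        rows.append((g.chrom, g.start, g.end, name, 0, g.strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    df = df.sort_values(["chrom", "start", "name"], kind="mergesort")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    genes = []
    for row in df.itertuples(index=False):
        parts = row.name.split("|")
        if len(parts) < 2:
            raise ValueError(f"annotation name field lacks a class label: {row.name!r}")
        genes.append(
            GeneAnnotation(
                row.chrom, int(row.start), int(row.end), row.strand,
                parts[0], parts[1], histone=(len(parts) > 2 and parts[2] == "histone"),
            )
        )
    return genes


def write_narrowpeak(peaks, path: str | Path) -> None:
    from .chip import Peak  # local import to avoid a cycle

    rows = [
        (p.chrom, p.start, p.end, p.name, int(round(p.score)), p.strand,
         p.signal, p.p_value, p.q_value, p.summit)
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)
    df = df.sort_values(["chrom", "start", "name"], kind="mergesort")
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.5g")


def read_narrowpeak(path: str | Path):
    from .chip import Peak

    try:
        df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                         dtype={"chrom": str, "name": str, "strand": str})
    except pd.errors.EmptyDataError:
        return []
    return [
        Peak(r.chrom, int(r.start), int(r.end), r.name, float(r.score), r.strand,
             float(r.signalValue), float(r.pValue), float(r.qValue), int(r.summit))
        for r in df.itertuples(index=False)
    ]


def write_bedgraph(track, path: str | Path) -> None:
    """Write a uniformly binned CoverageTrack as 4-column bedGraph."""
    rows = []
    for chrom in sorted(track.values):
        vals = track.values[chrom]
        bs = track.bin_size
        for i, v in enumerate(vals):
            rows.append((chrom, i * bs, (i + 1) * bs, float(v)))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path: str | Path, bin_size: int, chrom_lengths: dict[str, int] | None = None,
                  label: str = ""):
    """Read a bedGraph onto a uniform grid of ``bin_size`` (overlap-weighted mean)."""
    from .chip import CoverageTrack

    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    lengths = dict(chrom_lengths or {})
    for chrom, sub in df.groupby("chrom"):
        lengths.setdefault(chrom, int(sub["end"].max()))
    values = {}
    for chrom, length in lengths.items():
        nbins = -(-length // bin_size)
        acc = np.zeros(nbins)
        cov = np.zeros(nbins)
        sub = df[df["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            b0, b1 = int(row.start) // bin_size, -(-int(row.end) // bin_size)
            for b in range(b0, min(b1, nbins)):
                lo = max(int(row.start), b * bin_size)
                hi = min(int(row.end), (b + 1) * bin_size)
                acc[b] += row.value * (hi - lo)
                cov[b] += hi - lo
        with np.errstate(invalid="ignore"):
            vals = np.where(cov > 0, acc / np.maximum(cov, 1), 0.0)
        values[chrom] = vals
    return CoverageTrack(bin_size=bin_size, values=values, label=label)


def write_genome_meta(model, path: str | Path) -> None:
    import json

    meta = {
        "clusters": [
            {"name": c.name, "chrom": c.chrom, "start": c.start, "end": c.end}
            for c in model.clusters
        ],
        "metadata": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.metadata.items()
        },
    }
    Path(path).write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")


def load_genome_dir(path: str | Path):
    """Reconstruct a GenomeModel from genome.fa + annotation.bed + genome_meta.json."""
    import json

    from .genome import ClusterInterval, GenomeModel

    path = Path(path)
    meta = json.loads((path / "genome_meta.json").read_text())
    return GenomeModel(
        chromosomes=read_fasta(path / "genome.fa"),
        genes=read_annotation_bed(path / "annotation.bed"),
        clusters=[ClusterInterval(**c) for c in meta["clusters"]],
        metadata=meta["metadata"],
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
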