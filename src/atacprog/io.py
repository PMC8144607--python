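"""Reading and writing the pipeline's plain-text formats.

BED intervals are 0-based half-open; peak and atlas ids are
``chrom:start-end``.  Tables are tab-separated with a header unless the
format forbids one (BED).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .atlas import PeakAtlas, PeakInterval, PeakSet


def read_bed(path, sample_id: str | None = None) -> PeakSet:
    """Read a BED3+ / narrowPeak file as a canonical peak set.

    Only the first three columns are used; narrowPeak summit and score
    columns are ignored.
    """
    path = Path(path)
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {line!r}")
            ivs.append(PeakInterval(parts[0], int(parts[1]), int(parts[2])))
    return PeakSet(sample_id or path.stem, ivs)


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.peak_id}\n")


def write_atlas(atlas: PeakAtlas, path) -> None:
    write_bed(atlas.intervals, path)


def read_atlas(path) -> PeakAtlas:
    ps = read_bed(path)
    atlas = PeakAtlas(ps.intervals)
    atlas.assert_disjoint()
    return atlas


def read_fragments(path) -> pd.DataFrame:
    """Read fragments as BED6 (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return df


def read_counts(path) -> pd.DataFrame:
    """Peak x sample count matrix, rows indexed by ``chrom:start-end``."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="patient")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "class" in df.columns and "klass" not in df.columns:
        df = df.rename(columns={"class": "klass"})
    return df


def write_probes(probes: pd.DataFrame, path) -> None:
    probes.rename(columns={"klass": "class"}).to_csv(path, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    """Two-channel scan table: probe_id, cy5, cy3."""
    return pd.read_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    """Peak sequences keyed by record id (ids match atlas peak ids)."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_expression_lfc(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def read_gene_annotations(path) -> pd.DataFrame:
    """Gene TSS table with columns gene, chrom, tss."""
    return pd.read_csv(path, sep="\t")
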