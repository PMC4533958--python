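"""Readers/writers for the on-disk formats used throughout the pipeline.

Conventions: all interval files are BED6 (0-based half-open, strand in
column 6).  Per-sample read files are BED6 plus a 7th column carrying the
read sequence.  Everything else is TSV with a header row.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
READ_COLUMNS = BED6_COLUMNS + ["seq"]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                     dtype={"chrom": str, "start": int, "end": int,
                            "name": str, "strand": str})
    return df


def write_reads(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_reads(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=READ_COLUMNS,
                       dtype={"chrom": str, "start": int, "end": int,
                              "name": str, "strand": str, "seq": str})


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
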