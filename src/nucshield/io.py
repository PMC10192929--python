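"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based, half-open throughout (BED convention). FASTA goes
through Biopython; everything tabular goes through pandas.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path, description: str = "") -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=description) for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chromosome sizes file (name <tab> length)."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, length = line.split()[:2]
        sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 (optionally with a trailing sequence column).

    Lines starting with ``#`` or ``track`` are skipped.
    """
    rows = [
        line
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith(("#", "track"))
    ]
    if not rows:
        return pd.DataFrame(columns=BED6_COLUMNS)
    df = pd.read_csv(_io.StringIO("\n".join(rows)), sep="\t", header=None)
    ncol = df.shape[1]
    names = BED6_COLUMNS[: min(ncol, 6)] + (["seq"] if ncol == 7 else [])
    df.columns = names[:ncol]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    return df


def write_bed(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    cols = [c for c in BED6_COLUMNS + ["seq"] if c in df.columns]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.loc[:, cols].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path: str | Path) -> list[tuple[int, int]]:
    """Tab-separated bead-id pair list."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()[:2]
        pairs.append((int(a), int(b)))
    return pairs


def write_pairs(pairs: list[tuple[int, int]], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_windowed_counts(path: str | Path) -> pd.DataFrame:
    """chrom, start, end, early, late table (with header row)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_windowed_counts(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)
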