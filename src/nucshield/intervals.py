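"""Small interval routines on 0-based, half-open genomic intervals.

All functions operate on pandas DataFrames with at least ``chrom``,
``start`` and ``end`` columns. They are deliberately minimal: the package
needs interval merging, complements and midpoint containment, nothing more.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["merge_intervals", "complement", "points_in_intervals", "sort_intervals"]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chrom, start, end), resetting the index."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, merge_abutting: bool = False) -> pd.DataFrame:
    """Union of intervals per chromosome.

    With ``merge_abutting=False`` only strictly overlapping intervals are
    merged; book-ended intervals ([0,5) and [5,9)) stay separate. With
    ``merge_abutting=True`` book-ended intervals are merged too (the usual
    ``bedtools merge`` behaviour, appropriate for building masks).
    """
    if len(df) == 0:
        return df.loc[:, ["chrom", "start", "end"]].copy()
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, grp in sort_intervals(df).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            joins = s <= cur_e if merge_abutting else s < cur_e
            if joins:
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def complement(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Gaps not covered by ``df`` over each chromosome in ``chrom_sizes``.

    Input intervals must lie within the stated chromosome bounds.
    """
    merged = merge_intervals(df, merge_abutting=True)
    rows = []
    for chrom, size in chrom_sizes.items():
        grp = merged[merged["chrom"] == chrom]
        cursor = 0
        for s, e in zip(grp["start"], grp["end"]):
            if s < 0 or e > size:
                raise ValueError(f"interval [{s},{e}) outside {chrom} (size {size})")
            if s > cursor:
                rows.append((chrom, cursor, int(s)))
            cursor = max(cursor, int(e))
        if cursor < size:
            rows.append((chrom, cursor, size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def points_in_intervals(
    point_chroms: pd.Series, point_pos: pd.Series, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: does each point fall inside any (half-open) interval?

    ``intervals`` must be non-overlapping within each chromosome (merge
    first if unsure).
    """
    result = np.zeros(len(point_pos), dtype=bool)
    pos = np.asarray(point_pos)
    chroms = np.asarray(point_chroms)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] = pos[sel][ok] < ends[idx[ok]]
        result[sel] = ok
    return result
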