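"""Post-alignment processing of Damage-seq and XR-seq reads.

Damage-seq places the UV lesion two nucleotides upstream of the sequenced
read's 5' start. Each aligned read is therefore transformed into a 10-nt
damage window positioned so that the lesion dinucleotide occupies window
positions 5-6 in read orientation. XR-seq excision fragments are used
full-length; both assays are sorted and PCR-deduplicated on
(chrom, start, end, strand).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["extract_damage_windows", "sort_dedup", "DAMAGE_WINDOW_LEN"]

DAMAGE_WINDOW_LEN = 10


def extract_damage_windows(
    reads: pd.DataFrame, chrom_sizes: dict[str, int]
) -> tuple[pd.DataFrame, int]:
    """10-nt damage windows with the lesion at read-orientation positions 5-6.

    Plus-strand read [s, e) -> window [s-6, s+4); minus-strand read
    [s, e) -> window [e-4, e+6). Windows running past a chromosome end are
    dropped (a clipped window cannot hold positions 5-6); the number
    dropped is returned alongside the windows.
    """
    if len(reads) == 0:
        return reads.copy(), 0
    strands = reads["strand"]
    if strands.isna().any() or not strands.isin(["+", "-"]).all():
        raise ValueError("every read must carry a +/- strand")
    plus = strands == "+"
    w_start = np.where(plus, reads["start"] - 6, reads["end"] - 4)
    w_end = w_start + DAMAGE_WINDOW_LEN
    sizes = reads["chrom"].map(chrom_sizes)
    if sizes.isna().any():
        raise ValueError("read on a chromosome absent from chrom_sizes")
    keep = (w_start >= 0) & (w_end <= sizes.to_numpy())
    out = reads.loc[keep, ["chrom", "name", "score", "strand"]].copy()
    out["start"] = w_start[keep]
    out["end"] = w_end[keep]
    out = out.loc[:, ["chrom", "start", "end", "name", "score", "strand"]]
    return out.reset_index(drop=True), int((~keep).sum())


def sort_dedup(reads: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chrom, start, end, strand) and collapse exact duplicates.

    Strand is part of the key: identical intervals on opposite strands are
    distinct observations. Idempotent.
    """
    keys = ["chrom", "start", "end", "strand"]
    out = reads.drop_duplicates(subset=keys, keep="first")
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)
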