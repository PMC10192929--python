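"""Stratified re-analysis: genic vs intergenic, early vs late replication.

Reads are partitioned by where their midpoint falls (same rule as bead
assignment) and the radial analysis is re-run per stratum, to check that a
radial trend is not an artifact of transcription or replication-timing
geography.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome3d import BeadModel
from .intervals import complement, merge_intervals, points_in_intervals
from .radial import count_reads_per_bead, shell_comparison_report, shell_distributions

__all__ = [
    "merge_genes",
    "split_reads_by_mask",
    "call_replication_domains",
    "stratified_radial_analysis",
]


def merge_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Union of (possibly overlapping) gene intervals: the genic mask.

    Book-ended genes are merged too — the mask is a coverage set, and its
    complement within each chromosome is the intergenic space.
    """
    return merge_intervals(genes, merge_abutting=True)


def split_reads_by_mask(
    reads: pd.DataFrame, mask: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition reads into (inside-mask, outside-mask) by read midpoint.

    Exhaustive and exclusive: every read lands in exactly one part.
    """
    mid = (reads["start"].to_numpy() + reads["end"].to_numpy()) // 2
    inside = points_in_intervals(reads["chrom"], pd.Series(mid), mask)
    return (
        reads.loc[inside].reset_index(drop=True),
        reads.loc[~inside].reset_index(drop=True),
    )


def call_replication_domains(
    counts: pd.DataFrame, min_windows: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment early/late replication domains from windowed EdU counts.

    Per window, r = log2((early + 0.5) / (late + 0.5)); maximal runs of at
    least ``min_windows`` consecutive same-sign windows on one chromosome
    become domains labelled ``early`` (r > 0) or ``late`` (r < 0). Windows
    with r exactly 0 break runs. Returns (domains, per-window table with
    the log2 ratio).
    """
    req = {"chrom", "start", "end", "early", "late"}
    if not req.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(req)}")
    win = counts.sort_values(["chrom", "start"]).reset_index(drop=True).copy()
    win["log2_ratio"] = np.log2((win["early"] + 0.5) / (win["late"] + 0.5))
    sign = np.sign(win["log2_ratio"].to_numpy())
    rows = []
    for chrom, grp in win.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        # contiguity: windows must abut; a gap breaks the run
        run_start = 0
        positions = grp[["start", "end"]].to_numpy()
        s = sign[idx]
        k = 0
        while k <= len(idx):
            end_of_run = (
                k == len(idx)
                or s[k] != s[run_start]
                or s[k] == 0
                or (k > run_start and positions[k, 0] != positions[k - 1, 1])
            )
            if end_of_run:
                if k - run_start >= min_windows and s[run_start] != 0:
                    label = "early" if s[run_start] > 0 else "late"
                    rows.append(
                        (chrom, int(positions[run_start, 0]), int(positions[k - 1, 1]), label)
                    )
                run_start = k
            k += 1
    domains = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return domains, win


def stratified_radial_analysis(
    model: BeadModel,
    assignment: dict[int, str],
    read_sets: dict[str, pd.DataFrame],
    strata: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int] | None = None,
    include_complement: str | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Re-run the per-shell analysis on each read subset.

    ``strata`` maps stratum name -> interval mask; reads whose midpoint
    falls in the mask belong to the stratum. ``include_complement`` names
    an extra stratum holding everything outside the union of the given
    masks (e.g. "intergenic"); it requires ``chrom_sizes``. For each
    stratum and each read set, per-bead RPKM values are summarised per
    shell and the central shell is Welch-tested against the others.
    Returns stratum -> {"<set>_table", "<set>_summary", "<set>_report"}.
    """
    masks = dict(strata)
    if include_complement is not None:
        if chrom_sizes is None:
            raise ValueError("complement stratum requires chrom_sizes")
        union = merge_intervals(
            pd.concat(list(strata.values()), ignore_index=True), merge_abutting=True
        )
        masks[include_complement] = complement(union, chrom_sizes)
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for name, mask in masks.items():
        out: dict[str, pd.DataFrame] = {}
        for set_name, reads in read_sets.items():
            subset, _ = split_reads_by_mask(reads, mask)
            signal = count_reads_per_bead(subset, model)
            values = pd.Series(
                signal.table["rpkm"].to_numpy(), index=signal.table["bead_id"].to_numpy()
            )
            table, summary = shell_distributions(values, assignment, value_kind=set_name)
            report = shell_comparison_report(table)
            out[f"{set_name}_table"] = table
            out[f"{set_name}_summary"] = summary
            out[f"{set_name}_report"] = report
        results[name] = out
    return results
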