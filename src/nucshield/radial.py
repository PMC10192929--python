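"""Per-bead radial statistics: RPKM, observed/expected, double-normalized
repair, shell distributions and Welch's t-tests.

The unit of analysis is the bead (one merged TAD or inter-domain gap).
Reads are assigned to the bead containing their midpoint and converted to
RPKM (reads per kilobase of bead per million mapped reads). Real signal is
normalized by frequency-matched simulated signal (observed/expected),
which removes sequence-composition and copy-number bias; repair is further
normalized by damage (double normalization) to isolate repair efficiency
from the initial damage landscape. Distributions are summarised per 1-um
radial shell and the central shell "0-1" is tested against every other
shell with Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome3d import BeadModel

__all__ = [
    "BeadSignal",
    "WelchResult",
    "count_reads_per_bead",
    "rpkm",
    "observed_expected",
    "double_normalize",
    "shell_distributions",
    "welch_test",
    "shell_comparison_report",
]


@dataclass
class BeadSignal:
    """Per-bead read counts and RPKM."""

    table: pd.DataFrame  # columns: bead_id, count, rpkm
    total_mapped: int
    skipped: int  # reads on chromosomes absent from the model


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    n_x: int
    n_y: int


def count_reads_per_bead(reads: pd.DataFrame, model: BeadModel) -> BeadSignal:
    """Assign each read to the unique bead containing its midpoint.

    Midpoint = floor((start + end) / 2); bead intervals are half-open, so
    a midpoint on a bead's start belongs to that bead. Reads on
    chromosomes the model does not tile are skipped and counted.
    """
    beads = model.beads
    counts = np.zeros(len(beads), dtype=np.int64)
    skipped = 0
    mid = ((reads["start"].to_numpy() + reads["end"].to_numpy()) // 2).astype(np.int64)
    chroms = reads["chrom"].to_numpy()
    for chrom, grp in beads.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        idx = np.searchsorted(starts, mid[sel], side="right") - 1
        # per-chromosome tiling makes every in-bounds midpoint land in a bead
        ends = grp["end"].to_numpy()
        ok = (idx >= 0) & (mid[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
        np.add.at(counts, grp.index.to_numpy()[idx[ok]], 1)
        skipped += int((~ok).sum())
    known = set(beads["chrom"])
    skipped += int(sum(1 for c in chroms if c not in known))
    total = len(reads)
    lengths = model.lengths_bp
    r = np.array([rpkm(int(c), int(l), total) for c, l in zip(counts, lengths)])
    table = pd.DataFrame({"bead_id": beads["bead_id"].to_numpy(), "count": counts, "rpkm": r})
    return BeadSignal(table=table, total_mapped=total, skipped=skipped)


def rpkm(count: int, length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("region length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return count / (length_bp / 1e3) / (total_mapped / 1e6)


def _ratio(
    num: pd.DataFrame, den: pd.DataFrame, value: str = "rpkm"
) -> tuple[pd.Series, int]:
    merged = num.merge(den, on="bead_id", suffixes=("_num", "_den"))
    nonzero = merged[f"{value}_den"] > 0
    ratios = merged.loc[nonzero, f"{value}_num"] / merged.loc[nonzero, f"{value}_den"]
    ratios.index = merged.loc[nonzero, "bead_id"]
    return ratios, int((~nonzero).sum())


def observed_expected(obs: BeadSignal, sim: BeadSignal) -> tuple[pd.Series, int]:
    """Per-bead fold change observed RPKM / simulated ("expected") RPKM.

    Beads with zero expected signal are excluded; the exclusion count is
    returned alongside the bead_id-indexed ratio series.
    """
    if set(obs.table["bead_id"]) != set(sim.table["bead_id"]):
        raise ValueError("observed and simulated signals cover different beads")
    return _ratio(obs.table, sim.table)


def double_normalize(
    repair_ratio: pd.Series, damage_ratio: pd.Series
) -> tuple[pd.Series, int]:
    """(repair / repair-simulation) over (damage / damage-simulation).

    Both inputs are bead-indexed observed/expected ratios; beads missing
    from either, or with zero damage ratio, are excluded and counted.
    """
    common = repair_ratio.index.intersection(damage_ratio.index)
    excluded = len(repair_ratio.index.union(damage_ratio.index)) - len(common)
    dmg = damage_ratio.loc[common]
    nonzero = dmg > 0
    excluded += int((~nonzero).sum())
    values = repair_ratio.loc[common][nonzero] / dmg[nonzero]
    return values, excluded


def shell_distributions(
    values: pd.Series, assignment: dict[int, str], value_kind: str = "value"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shell-labelled per-bead values plus per-shell summaries.

    ``values`` is indexed by bead_id. Returns (table, summary): the table
    has one row per bead (bead_id, shell, value, kind); the summary has
    n/median/mean/sd per shell, with NA stats for empty shells. Summaries
    are unweighted across beads.
    """
    missing = [b for b in values.index if int(b) not in assignment]
    if missing:
        raise ValueError(f"beads without a shell: {missing[:5]}")
    table = pd.DataFrame(
        {
            "bead_id": values.index.to_numpy(),
            "shell": [assignment[int(b)] for b in values.index],
            "value": values.to_numpy(),
            "kind": value_kind,
        }
    )
    shells = sorted(set(assignment.values()), key=lambda s: int(s.split("-")[0]))
    rows = []
    for shell in shells:
        v = table.loc[table["shell"] == shell, "value"]
        if len(v) == 0:
            rows.append((shell, 0, np.nan, np.nan, np.nan))
        else:
            rows.append((shell, len(v), float(v.median()), float(v.mean()), float(v.std(ddof=1))))
    summary = pd.DataFrame(rows, columns=["shell", "n", "median", "mean", "sd"])
    return table, summary


def welch_test(x, y) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two values")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return WelchResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0, n_x=len(x), n_y=len(y))
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue), n_x=len(x), n_y=len(y)
    )


def shell_comparison_report(table: pd.DataFrame, reference_shell: str = "0-1") -> pd.DataFrame:
    """Welch tests of the central shell against every other shell.

    One row per (kind, compared shell): t, df, p and both shell medians.
    Comparisons with fewer than two beads on either side are reported as
    NA rather than dropped.
    """
    rows = []
    for kind, grp in table.groupby("kind", sort=False):
        ref = grp.loc[grp["shell"] == reference_shell, "value"].to_numpy()
        others = sorted(
            set(grp["shell"]) - {reference_shell}, key=lambda s: int(s.split("-")[0])
        )
        for shell in others:
            other = grp.loc[grp["shell"] == shell, "value"].to_numpy()
            med_ref = float(np.median(ref)) if len(ref) else np.nan
            med_other = float(np.median(other)) if len(other) else np.nan
            if len(ref) >= 2 and len(other) >= 2:
                try:
                    w = welch_test(ref, other)
                    t, df, p = w.t, w.df, w.p
                except ValueError:
                    t = df = p = np.nan
            else:
                t = df = p = np.nan
            rows.append((kind, reference_shell, shell, t, df, p, med_ref, med_other))
    return pd.DataFrame(
        rows,
        columns=[
            "kind",
            "shell_ref",
            "shell",
            "t",
            "df",
            "p",
            "median_ref",
            "median",
        ],
    )
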