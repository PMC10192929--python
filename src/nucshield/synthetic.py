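"""Synthetic inputs with known planted structure.

Every input the pipeline consumes — genome FASTA, domain (TAD) lists,
significant bead-bead interaction pairs, damage/repair/input read sets,
early/late replication counts and gene intervals — can be generated here
with controllable ground truth, so the downstream stages (3D model, read
simulation, radial statistics) can be tested for recovery of what was
planted.

Planted structure available:

* a linear 5'->3' gradient in TT/TC dipyrimidine density along a
  chromosome (the sequence feature UV lesions form at),
* a per-radial-shell read-rate multiplier (an enrichment gradient across
  the modeled nucleus),
* an excess of bead-bead interactions within a chosen "central" bead set,
* early/late replication domains with a chosen log2 effect size.

All generators take an explicit seed and are byte-reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "RadialEffectSpec",
    "generate_genome",
    "generate_domains",
    "generate_genes",
    "generate_interactions",
    "generate_reads",
    "generate_edu_counts",
    "dipyrimidine_sites",
    "xr_length_distribution",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_SHELL_RE = re.compile(r"^\d+-\d+$")


@dataclass
class GenomeSpec:
    """Parameters of a synthetic genome.

    chrom_sizes: chromosome name -> length in bp.
    base_composition: probabilities of A, C, G, T (must sum to 1).
    dipyrimidine_gradient: optional chromosome -> multiplier g; TT/TC
        density rises linearly from ``dipyrimidine_rate`` at the 5' end to
        ``g * dipyrimidine_rate`` at the 3' end. On gradient chromosomes
        every TT/TC occurrence is planted (background occurrences are
        rewritten), so the realised density equals the requested profile.
    dipyrimidine_rate: baseline planted TT/TC starts per bp on gradient
        chromosomes.
    """

    chrom_sizes: dict[str, int]
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    dipyrimidine_gradient: dict[str, float] = field(default_factory=dict)
    dipyrimidine_rate: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if any(p < 0 for p in self.base_composition):
            raise ValueError("base composition must be non-negative")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for chrom, g in self.dipyrimidine_gradient.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"gradient on unknown chromosome {chrom}")
            if g <= 0:
                raise ValueError("gradient multiplier must be positive")
            if 2.0 * self.dipyrimidine_rate * max(g, 1.0) > 1.0:
                raise ValueError("dipyrimidine rate x gradient too dense to plant")


@dataclass
class RadialEffectSpec:
    """Planted radial read-enrichment: shell label -> rate multiplier."""

    per_shell_multiplier: dict[str, float]
    baseline_rate: float = 1.0  # reads per kb, used when n_reads is derived

    def __post_init__(self) -> None:
        for label, m in self.per_shell_multiplier.items():
            if not _SHELL_RE.match(label):
                raise ValueError(f"malformed shell label {label!r}")
            if m <= 0:
                raise ValueError("shell multipliers must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")

    def multiplier(self, label: str) -> float:
        return self.per_shell_multiplier.get(label, 1.0)


def _iid_sequence(n: int, comp, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(comp, dtype=float))


def _plant_gradient(
    codes: np.ndarray, rate: float, gradient: float, comp, rng: np.random.Generator
) -> np.ndarray:
    """Overwrite a sequence so its TT/TC starts follow a linear density.

    Dimers are planted in non-overlapping 2-bp slots; afterwards every
    accidental TT/TC outside a planted slot is removed by rewriting one of
    its bases to A or G, so the realised TT/TC density is exactly the
    planted profile.
    """
    L = len(codes)
    n_slots = L // 2
    slot_pos = np.arange(n_slots) * 2
    density = rate * (1.0 + (gradient - 1.0) * slot_pos / max(L - 1, 1))
    plant = rng.random(n_slots) < 2.0 * density  # one dimer covers 2 bp
    starts = slot_pos[plant]
    # T=3, C=1 in the ACGT code; second base T or C with equal chance,
    # except that a dimer directly followed by another planted dimer is
    # forced to TC — a TT running into a planted T would form a cross-slot
    # TT whose cleanup would destroy a planted base
    second = np.where(rng.random(len(starts)) < 0.5, 3, 1)
    followed = np.append(plant[1:], False)[plant]  # planted slot with planted right neighbor
    second[followed] = 1
    codes[starts] = 3
    codes[starts + 1] = second
    planted = np.zeros(L, dtype=bool)
    planted[starts] = True

    comp = np.asarray(comp, dtype=float)
    p_ag = comp[[0, 2]]
    p_ag = p_ag / p_ag.sum() if p_ag.sum() > 0 else np.array([0.5, 0.5])
    for _ in range(8):  # converges in 1-2 passes
        first_t = codes[:-1] == 3
        second_py = (codes[1:] == 3) | (codes[1:] == 1)
        viol = np.flatnonzero(first_t & second_py & ~planted[:-1])
        if len(viol) == 0:
            break
        # if the violating pair runs into a planted dimer start, rewrite the
        # first base instead of destroying the dimer
        into_planted = planted[viol + 1]
        fix_pos = np.where(into_planted, viol, viol + 1)
        codes[fix_pos] = np.where(rng.random(len(fix_pos)) < p_ag[0], 0, 2)
    return codes


def generate_genome(spec: GenomeSpec, seed: int = 0) -> dict[str, str]:
    """Synthesize one sequence per chromosome, honouring any planted
    dipyrimidine gradient. Identical seed gives identical sequences."""
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    for chrom, size in spec.chrom_sizes.items():
        codes = _iid_sequence(size, spec.base_composition, rng)
        if chrom in spec.dipyrimidine_gradient:
            codes = _plant_gradient(
                codes,
                spec.dipyrimidine_rate,
                spec.dipyrimidine_gradient[chrom],
                spec.base_composition,
                rng,
            )
        genome[chrom] = _BASES[codes].tobytes().decode("ascii")
    return genome


def _allocate(rng: np.random.Generator, n: int, weights: np.ndarray) -> np.ndarray:
    return rng.multinomial(n, weights / weights.sum())


def generate_domains(
    chrom_sizes: dict[str, int],
    n_domains: int,
    size_range: tuple[int, int] = (50_000, 200_000),
    seed: int = 0,
    allow_overlap: bool = False,
) -> pd.DataFrame:
    """Random domain intervals, sorted; non-overlapping unless asked.

    With ``allow_overlap=True`` at least one overlapping pair is present
    (when ``n_domains >= 2``), so merge handling is exercised downstream.
    Raises when the requested domains cannot fit.
    """
    lo, hi = size_range
    if lo <= 0 or hi < lo:
        raise ValueError("bad size range")
    if max(chrom_sizes.values(), default=0) < hi:
        raise ValueError("size range exceeds every chromosome")
    if n_domains == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rng = np.random.default_rng(seed)
    names = list(chrom_sizes)
    sizes_arr = np.array([chrom_sizes[c] for c in names], dtype=float)
    alloc = _allocate(rng, n_domains, sizes_arr)
    rows = []
    for chrom, k in zip(names, alloc):
        if k == 0:
            continue
        L = chrom_sizes[chrom]
        widths = rng.integers(lo, hi + 1, size=k)
        if allow_overlap:
            starts = rng.integers(0, L - widths + 1)
            if k >= 2:  # force one overlapping pair
                order = np.argsort(starts)
                a, b = order[0], order[1]
                starts[b] = min(starts[a] + widths[a] // 2, L - widths[b])
        else:
            free = L - int(widths.sum())
            if free < 0:
                raise ValueError(
                    f"{k} domains of up to {hi} bp do not fit in {chrom} ({L} bp)"
                )
            gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
            starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(widths[:-1])])
        for s, w in zip(starts, widths):
            rows.append((chrom, int(s), int(s + w)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def generate_genes(
    chrom_sizes: dict[str, int],
    n_genes: int,
    size_range: tuple[int, int] = (5_000, 100_000),
    seed: int = 0,
    allow_overlap: bool = True,
) -> pd.DataFrame:
    """Random gene intervals; overlapping by default (genes do overlap, and
    the genic mask is built by merging them)."""
    return generate_domains(chrom_sizes, n_genes, size_range, seed, allow_overlap)


def generate_interactions(
    bead_ids,
    n_pairs: int,
    central_set=None,
    central_excess: float = 0.8,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Distinct unordered bead-id pairs, optionally concentrated within a
    chosen bead set (plants radial structure for the placement optimizer).

    ``central_excess`` is the fraction of pairs drawn from within
    ``central_set`` (capped by the number of distinct within-set pairs).
    """
    ids = np.asarray(sorted(set(int(b) for b in bead_ids)))
    n = len(ids)
    possible = n * (n - 1) // 2
    if n_pairs > possible:
        raise ValueError(f"{n_pairs} pairs requested but only {possible} distinct pairs exist")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    if central_set is not None and n_pairs > 0:
        central = np.asarray(sorted(set(int(b) for b in central_set)))
        if not set(central).issubset(set(ids)):
            raise ValueError("central set contains unknown bead ids")
        pool = [
            (int(central[i]), int(central[j]))
            for i in range(len(central))
            for j in range(i + 1, len(central))
        ]
        n_central = min(int(round(central_excess * n_pairs)), len(pool))
        take = rng.choice(len(pool), size=n_central, replace=False)
        chosen.update(pool[t] for t in take)
    while len(chosen) < n_pairs:
        a, b = rng.choice(n, size=2, replace=False)
        pair = (int(ids[min(a, b)]), int(ids[max(a, b)]))
        chosen.add(pair)
    out = list(chosen)
    rng.shuffle(out)
    return out


def dipyrimidine_sites(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Start positions of TT/TC dimers on the plus strand and of their
    minus-strand equivalents (genomic AA/GA, which read TT/TC on minus)."""
    codes = np.frombuffer(seq.encode("ascii"), dtype="S1")
    first = codes[:-1]
    second = codes[1:]
    plus = np.flatnonzero((first == b"T") & ((second == b"T") | (second == b"C")))
    minus = np.flatnonzero(((first == b"A") | (first == b"G")) & (second == b"A"))
    return plus, minus


def xr_length_distribution(mode: int = 26, lo: int = 20, hi: int = 30) -> dict[int, float]:
    """Truncated, mode-peaked excision-fragment length distribution."""
    lengths = np.arange(lo, hi + 1)
    w = np.exp(-((lengths - mode) ** 2) / (2 * 2.5**2))
    w /= w.sum()
    return {int(l): float(p) for l, p in zip(lengths, w)}


_COMPL = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPL)[::-1]


def fetch_sequences(reads: pd.DataFrame, genome: dict[str, str]) -> pd.Series:
    """Read-orientation sequences (reverse-complemented on minus strand)."""
    seqs = []
    for chrom, s, e, strand in zip(reads["chrom"], reads["start"], reads["end"], reads["strand"]):
        frag = genome[chrom][int(s) : int(e)]
        seqs.append(_revcomp(frag) if strand == "-" else frag)
    return pd.Series(seqs, index=reads.index, name="seq")


def _draw_lengths(rng, n, read_length, length_dist):
    if length_dist is None:
        return np.full(n, int(read_length))
    ls = np.array(sorted(length_dist))
    ps = np.array([length_dist[int(l)] for l in ls], dtype=float)
    return ls[rng.choice(len(ls), size=n, p=ps / ps.sum())]


def generate_reads(
    beads: pd.DataFrame,
    kind: str,
    n_reads: int,
    seed: int = 0,
    effect: RadialEffectSpec | None = None,
    shell_map: dict[int, str] | None = None,
    genome: dict[str, str] | None = None,
    chrom_sizes: dict[str, int] | None = None,
    read_length: int = 40,
    length_dist: dict[int, float] | None = None,
    purity: float = 0.95,
    with_sequences: bool = False,
) -> pd.DataFrame:
    """Sample strand-aware reads over a bead partition.

    Per-bead expected counts are proportional to bead weight times the
    shell multiplier of the bead (weight = dipyrimidine-site count for
    damage reads when a genome is given, genomic span otherwise).

    kind:
        ``damage`` — reads start two nucleotides downstream of a TT/TC
        lesion (so the 10-nt damage window centred per the Damage-seq
        convention holds the dimer at positions 5-6), with probability
        ``purity``; requires ``genome``.
        ``repair`` — full-length excision-like reads; lengths from
        ``length_dist`` (default truncated 20-30 nt, mode 26).
        ``input`` — composition-unbiased uniform background reads.
    """
    if kind not in {"damage", "repair", "input"}:
        raise ValueError(f"unknown read kind {kind!r}")
    if effect is not None and shell_map is None:
        raise ValueError("a bead->shell map is required when a radial effect is planted")
    if kind == "damage" and genome is None:
        raise ValueError("damage reads require a genome to place lesions")
    if kind == "repair" and length_dist is None:
        length_dist = xr_length_distribution()
    rng = np.random.default_rng(seed)
    beads = beads.reset_index(drop=True)
    if chrom_sizes is None:
        if genome is not None:
            chrom_sizes = {c: len(s) for c, s in genome.items()}
        else:
            chrom_sizes = beads.groupby("chrom")["end"].max().to_dict()

    site_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if kind == "damage":
        for chrom in beads["chrom"].unique():
            site_cache[chrom] = dipyrimidine_sites(genome[chrom])

    weights = np.zeros(len(beads), dtype=float)
    for i, row in beads.iterrows():
        if kind == "damage":
            plus, minus = site_cache[row["chrom"]]
            w = float(
                (plus >= row["start"]).sum()
                - (plus >= row["end"]).sum()
                + (minus >= row["start"]).sum()
                - (minus >= row["end"]).sum()
            )
        else:
            w = float(row["end"] - row["start"])
        if effect is not None:
            w *= effect.multiplier(shell_map[int(row["bead_id"])])
        weights[i] = w
    if weights.sum() <= 0:
        raise ValueError("no sampleable weight in any bead")
    counts = rng.multinomial(n_reads, weights / weights.sum())

    chroms, starts, ends, strands = [], [], [], []
    for i, row in beads.iterrows():
        k = int(counts[i])
        if k == 0:
            continue
        chrom = row["chrom"]
        size = chrom_sizes[chrom]
        lens = _draw_lengths(rng, k, read_length, length_dist)
        if kind == "damage":
            lmax = int(lens.max())
            plus_all, minus_all = site_cache[chrom]
            plus = plus_all[(plus_all >= row["start"]) & (plus_all < row["end"])]
            minus = minus_all[(minus_all >= row["start"]) & (minus_all < row["end"])]
            # keep only lesion sites whose read and 10-nt window fit the chromosome
            plus = plus[(plus >= 4) & (plus + 2 + lmax <= size)]
            minus = minus[(minus >= lmax) & (minus + 6 <= size)]
            on_site = rng.random(k) < purity
            s_arr = np.empty(k, dtype=np.int64)
            str_arr = np.empty(k, dtype="U1")
            n_sites = len(plus) + len(minus)
            for j in range(k):
                L = int(lens[j])
                if on_site[j] and n_sites > 0:
                    pick = int(rng.integers(n_sites))
                    if pick < len(plus):
                        p = int(plus[pick])
                        s, strand = p + 2, "+"  # lesion 2 nt upstream of 5' start
                    else:
                        p = int(minus[pick - len(plus)])
                        s, strand = p - L, "-"  # lesion 2 nt past the 3' end (genomic right)
                else:
                    s = int(rng.integers(row["start"], max(row["end"] - L, row["start"]) + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                s = min(max(s, 0), size - L)
                s_arr[j] = s
                str_arr[j] = strand
            e_arr = s_arr + lens
        else:
            hi = np.maximum(row["end"] - lens, row["start"])
            s_arr = rng.integers(row["start"], hi + 1)
            s_arr = np.minimum(np.maximum(s_arr, 0), np.array(size) - lens)
            e_arr = s_arr + lens
            str_arr = np.where(rng.random(k) < 0.5, "+", "-")
        chroms.extend([chrom] * k)
        starts.extend(s_arr.tolist())
        ends.extend(e_arr.tolist())
        strands.extend(list(str_arr))

    out = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "name": [f"{kind}_{i}" for i in range(len(chroms))],
            "score": 0,
            "strand": strands,
        }
    )
    # present reads in a seeded shuffle rather than bead order
    out = out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    if with_sequences:
        if genome is None:
            raise ValueError("sequences requested but no genome given")
        out["seq"] = fetch_sequences(out, genome)
    return out


def generate_edu_counts(
    chrom_sizes: dict[str, int],
    replication_domains: pd.DataFrame,
    window: int = 50_000,
    depth: float = 100.0,
    log2_effect: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Windowed early/late replication read counts with a planted effect.

    ``replication_domains`` carries chrom/start/end/label rows (label
    ``early`` or ``late``). A window whose midpoint falls in an early
    domain has E[log2(early/late)] = +``log2_effect``; late domains get the
    opposite sign; elsewhere the ratio is balanced. Counts are Poisson with
    mean ``depth`` per track. Trailing windows that do not fill ``window``
    bp are emitted with ``partial=True``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, size in chrom_sizes.items():
        edges = list(range(0, size, window)) + [size]
        doms = replication_domains[replication_domains["chrom"] == chrom]
        for s, e in zip(edges[:-1], edges[1:]):
            mid = (s + e) // 2
            hit = doms[(doms["start"] <= mid) & (mid < doms["end"])]
            delta = 0.0
            if len(hit):
                delta = log2_effect if hit["label"].iloc[0] == "early" else -log2_effect
            frac = (e - s) / window
            early = rng.poisson(depth * frac * 2.0 ** (delta / 2.0))
            late = rng.poisson(depth * frac * 2.0 ** (-delta / 2.0))
            rows.append((chrom, s, e, int(early), int(late), e - s < window))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "early", "late", "partial"])
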