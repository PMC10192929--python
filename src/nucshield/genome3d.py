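"""Bead-per-domain 3D nucleus model with radial shell partitioning.

Each chromosome is represented as a chain of spherical beads: one bead per
merged contact domain (TAD) and one per inter-domain gap, so the beads tile
the chromosome. Bead volumes are proportional to the genomic span they
represent and are scaled so that together they occupy a fixed fraction
(default 15%) of a spherical nucleus (default 10 um diameter). Beads are
placed by Monte Carlo minimisation of a constraint loss that pulls
significantly interacting bead pairs together, keeps the chain connected,
forbids overlaps and confines beads to the nucleus. Placed beads are then
binned into concentric 1-um radial shells ("0-1" ... "4-5") by the distance
of their centre from the nucleus centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import merge_intervals, sort_intervals

__all__ = [
    "BeadModel",
    "build_bead_partition",
    "scale_bead_radii",
    "loss",
    "optimize_model",
    "assign_shells",
    "shell_labels",
    "export_model",
    "load_model",
    "place_on_radii",
    "cycle_shell_layout",
    "map_interactions_to_beads",
]


@dataclass
class BeadModel:
    """Ordered beads tiling a genome inside a spherical nucleus.

    beads: DataFrame with columns bead_id, chrom, start, end, kind
        (``domain`` or ``gap``); per chromosome the intervals are contiguous
        and non-overlapping and tile [0, chrom length).
    nucleus_radius: um (default 5.0, a 10-um-diameter nucleus).
    occupancy: fraction of nuclear volume the beads jointly occupy.
    radii: per-bead radius in um (set by :func:`scale_bead_radii`).
    coords: (n, 3) bead centres in um, or None before placement.
    """

    beads: pd.DataFrame
    nucleus_radius: float = 5.0
    occupancy: float = 0.15
    radii: np.ndarray | None = None
    coords: np.ndarray | None = None
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.beads["end"] - self.beads["start"]).to_numpy()

    def chain_pairs(self) -> np.ndarray:
        """Index pairs of consecutive beads within each chromosome."""
        pairs = []
        for _, grp in self.beads.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            pairs.extend(zip(idx[:-1], idx[1:]))
        return np.array(pairs, dtype=int).reshape(-1, 2)


def build_bead_partition(domains: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Tile each chromosome with merged-domain beads and gap beads.

    Overlapping domains are merged into single beads; abutting domains stay
    separate. Regions not covered by any domain become gap beads. Raises if
    a domain extends beyond its chromosome.
    """
    for _, row in domains.iterrows():
        if row["chrom"] not in chrom_sizes:
            raise ValueError(f"domain on unknown chromosome {row['chrom']}")
        if row["start"] < 0 or row["end"] > chrom_sizes[row["chrom"]]:
            raise ValueError(
                f"domain [{row['start']},{row['end']}) outside {row['chrom']}"
            )
        if row["end"] <= row["start"]:
            raise ValueError("empty domain interval")
    merged = merge_intervals(domains, merge_abutting=False) if len(domains) else domains
    rows = []
    for chrom, size in chrom_sizes.items():
        grp = (
            sort_intervals(merged[merged["chrom"] == chrom])
            if len(merged)
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        cursor = 0
        for s, e in zip(grp.get("start", []), grp.get("end", [])):
            if s > cursor:
                rows.append((chrom, cursor, int(s), "gap"))
            rows.append((chrom, int(s), int(e), "domain"))
            cursor = int(e)
        if cursor < size:
            rows.append((chrom, cursor, size, "gap"))
    beads = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind"])
    beads.insert(0, "bead_id", np.arange(len(beads)))
    return beads


def scale_bead_radii(
    beads: pd.DataFrame, nucleus_diameter_um: float = 10.0, occupancy: float = 0.15
) -> np.ndarray:
    """Radii (um) such that bead volume is proportional to bead bp and the
    total equals ``occupancy`` times the nucleus volume."""
    if nucleus_diameter_um <= 0 or occupancy <= 0:
        raise ValueError("nucleus diameter and occupancy must be positive")
    lengths = (beads["end"] - beads["start"]).to_numpy(dtype=float)
    total_bp = lengths.sum()
    if total_bp <= 0:
        raise ValueError("partition has no genomic span")
    R = nucleus_diameter_um / 2.0
    v_nucleus = 4.0 / 3.0 * math.pi * R**3
    volumes = occupancy * v_nucleus * lengths / total_bp
    return (3.0 * volumes / (4.0 * math.pi)) ** (1.0 / 3.0)


def map_interactions_to_beads(
    interval_pairs: list[tuple[tuple[str, int, int], tuple[str, int, int]]],
    beads: pd.DataFrame,
) -> list[tuple[int, int]]:
    """Map genomic-interval pairs to the bead ids containing their midpoints."""

    def locate(chrom: str, start: int, end: int) -> int:
        mid = (start + end) // 2
        grp = beads[beads["chrom"] == chrom]
        hit = grp[(grp["start"] <= mid) & (mid < grp["end"])]
        if len(hit) != 1:
            raise ValueError(f"no bead contains {chrom}:{mid}")
        return int(hit["bead_id"].iloc[0])

    return [(locate(*a), locate(*b)) for a, b in interval_pairs]


def _loss_terms(
    coords: np.ndarray,
    radii: np.ndarray,
    interactions: np.ndarray,
    chain: np.ndarray,
    R: float,
) -> tuple[float, float, float, float]:
    n = len(coords)
    # pairwise overlap penalty over all bead pairs
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    rsum = radii[:, None] + radii[None, :]
    overlap = np.triu(np.maximum(0.0, rsum - dist), k=1)
    np.fill_diagonal(overlap, 0.0)
    t_overlap = float((overlap**2).sum())

    def gap_sq(pairs: np.ndarray) -> float:
        if len(pairs) == 0:
            return 0.0
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        g = np.maximum(0.0, d - (radii[pairs[:, 0]] + radii[pairs[:, 1]]))
        return float((g**2).sum())

    t_inter = gap_sq(interactions)
    t_chain = gap_sq(chain)
    out = np.maximum(0.0, np.linalg.norm(coords, axis=1) + radii - R)
    t_nuc = float((out**2).sum())
    return t_inter, t_overlap, t_chain, t_nuc


def loss(
    model: BeadModel,
    interactions: list[tuple[int, int]],
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> float:
    """Constraint loss of a placed model.

    Terms (each a sum of squared violations, weighted by ``weights`` =
    (interaction, overlap, chain, nucleus)):

    * interacting pairs further apart than touching,
    * any pair of beads overlapping,
    * chain-adjacent beads further apart than touching,
    * beads protruding beyond the nuclear envelope.

    Zero iff all constraints are satisfied.
    """
    if model.coords is None or model.radii is None:
        raise ValueError("model must have radii and coordinates")
    inter = np.array(interactions, dtype=int).reshape(-1, 2)
    terms = _loss_terms(model.coords, model.radii, inter, model.chain_pairs(), model.nucleus_radius)
    return float(sum(w * t for w, t in zip(weights, terms)))


def _initial_placement(model: BeadModel, rng: np.random.Generator) -> np.ndarray:
    """Random contained start: chains laid out as clipped random walks."""
    R = model.nucleus_radius
    radii = model.radii
    coords = np.zeros((model.n_beads, 3))
    for _, grp in model.beads.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        # random point with the first bead fully inside
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        coords[idx[0]] = u * rng.uniform(0, max(R - radii[idx[0]], 0.0))
        for prev, cur in zip(idx[:-1], idx[1:]):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            pos = coords[prev] + step * (radii[prev] + radii[cur])
            norm = np.linalg.norm(pos)
            limit = max(R - radii[cur], 1e-9)
            if norm > limit:
                pos = pos / norm * limit
            coords[cur] = pos
    return coords


def _bead_loss(
    i: int,
    coords: np.ndarray,
    radii: np.ndarray,
    partners_inter: dict[int, list[int]],
    partners_chain: dict[int, list[int]],
    R: float,
    w: tuple[float, float, float, float],
) -> float:
    """Loss contribution of all terms involving bead ``i``."""
    ci = coords[i]
    d_all = np.linalg.norm(coords - ci, axis=1)
    rsum = radii + radii[i]
    ov = np.maximum(0.0, rsum - d_all)
    ov[i] = 0.0
    total = w[1] * float((ov**2).sum())
    for lst, wk in ((partners_inter.get(i, []), w[0]), (partners_chain.get(i, []), w[2])):
        for j in lst:
            gap = max(0.0, d_all[j] - rsum[j])
            total += wk * gap * gap
    total += w[3] * max(0.0, np.linalg.norm(ci) + radii[i] - R) ** 2
    return total


def optimize_model(
    model: BeadModel,
    interactions: list[tuple[int, int]],
    n_steps: int = 20000,
    step_size_um: float = 0.1,
    t0: float = 1.0,
    cooling: float = 0.999,
    t_floor: float = 0.0,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    seed: int = 0,
) -> tuple[BeadModel, np.ndarray]:
    """Metropolis Monte Carlo placement of the beads.

    Single-bead Gaussian displacement proposals; geometric cooling from
    ``t0`` by ``cooling`` per step down to ``t_floor`` (a floor of 0 gives a
    greedy tail, in which the accepted-state loss is non-increasing).
    Returns the placed model and the loss trace of accepted states
    (including the initial one). ``n_steps=0`` returns the initial random
    placement.
    """
    if model.radii is None:
        raise ValueError("scale radii before optimizing")
    rng = np.random.default_rng(seed)
    coords = (
        model.coords.copy() if model.coords is not None else _initial_placement(model, rng)
    )
    radii = model.radii
    R = model.nucleus_radius
    inter = np.array(interactions, dtype=int).reshape(-1, 2)
    chain = model.chain_pairs()
    p_inter: dict[int, list[int]] = {}
    p_chain: dict[int, list[int]] = {}
    for pairs, store in ((inter, p_inter), (chain, p_chain)):
        for a, b in pairs:
            store.setdefault(int(a), []).append(int(b))
            store.setdefault(int(b), []).append(int(a))

    terms = _loss_terms(coords, radii, inter, chain, R)
    total = float(sum(w * t for w, t in zip(weights, terms)))
    trace = [total]
    temp = t0
    n = len(coords)
    for _ in range(n_steps):
        i = int(rng.integers(n))
        old = coords[i].copy()
        before = _bead_loss(i, coords, radii, p_inter, p_chain, R, weights)
        coords[i] = old + rng.normal(scale=step_size_um, size=3)
        after = _bead_loss(i, coords, radii, p_inter, p_chain, R, weights)
        delta = after - before
        accept = delta <= 0 or (temp > 0 and rng.random() < math.exp(-delta / temp))
        if accept:
            total += delta
            trace.append(total)
        else:
            coords[i] = old
        temp = max(temp * cooling, t_floor)
    placed = BeadModel(
        beads=model.beads,
        nucleus_radius=model.nucleus_radius,
        occupancy=model.occupancy,
        radii=radii,
        coords=coords,
        chrom_sizes=model.chrom_sizes,
    )
    return placed, np.asarray(trace)


def fit_model(
    model: BeadModel,
    interactions: list[tuple[int, int]],
    n_steps: int = 60000,
    polish_steps: int = 20000,
    seed: int = 0,
    **kwargs,
) -> tuple[BeadModel, np.ndarray]:
    """Annealed placement followed by a fine-step greedy polish.

    The polish phase (step 0.02 um, temperature 0) settles residual
    envelope protrusions and overlaps after the annealed search. Returns
    the placed model and the concatenated accepted-loss trace.
    """
    placed, trace = optimize_model(model, interactions, n_steps=n_steps, seed=seed, **kwargs)
    polished, trace2 = optimize_model(
        placed,
        interactions,
        n_steps=polish_steps,
        step_size_um=0.02,
        t0=0.0,
        seed=seed + 1,
        weights=kwargs.get("weights", (1.0, 1.0, 1.0, 1.0)),
    )
    return polished, np.concatenate([trace, trace2[1:]])


def shell_labels(nucleus_radius: float = 5.0, width_um: float = 1.0) -> list[str]:
    """Labels of the concentric shells partitioning [0, R)."""
    n = int(math.ceil(nucleus_radius / width_um))
    return [f"{k}-{k + 1}" for k in range(n)]


def assign_shells(model: BeadModel, shell_width_um: float = 1.0) -> dict[int, str]:
    """Bin each bead into the radial shell containing its centre.

    Shells are half-open [k, k+1) um bins of centre distance; a bead whose
    centre lies at or beyond the nuclear envelope raises (containment should
    prevent this).
    """
    if model.coords is None:
        raise ValueError("model must be placed before shell assignment")
    d = np.linalg.norm(model.coords, axis=1)
    if np.any(d >= model.nucleus_radius):
        bad = model.beads["bead_id"].to_numpy()[d >= model.nucleus_radius]
        raise ValueError(f"bead centres outside nucleus: {bad[:5].tolist()}")
    k = np.floor(d / shell_width_um).astype(int)
    ids = model.beads["bead_id"].to_numpy()
    return {int(b): f"{ki}-{ki + 1}" for b, ki in zip(ids, k)}


def place_on_radii(model: BeadModel, radii_um: np.ndarray, seed: int = 0) -> BeadModel:
    """Deterministic layout helper: place each bead at the given centre
    distance in a random direction.

    Used for planted-structure studies where the shell of every bead must be
    controlled exactly, bypassing optimization.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(model.n_beads, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = dirs * np.asarray(radii_um, dtype=float)[:, None]
    return BeadModel(
        beads=model.beads,
        nucleus_radius=model.nucleus_radius,
        occupancy=model.occupancy,
        radii=model.radii,
        coords=coords,
        chrom_sizes=model.chrom_sizes,
    )


def cycle_shell_layout(model: BeadModel, seed: int = 0, width_um: float = 1.0) -> BeadModel:
    """Place beads round-robin across shells (at mid-shell radii).

    Gives every shell an equal bead count — a synthetic layout for
    calibration and recovery studies, not a physical placement.
    """
    labels = shell_labels(model.nucleus_radius, width_um)
    mids = np.array([(i + 0.5) * width_um for i in range(len(labels))])
    radii = mids[np.arange(model.n_beads) % len(labels)]
    return place_on_radii(model, radii, seed=seed)


def export_model(model: BeadModel, assignment: dict[int, str], path) -> None:
    """Write the placed model as a round-trippable TSV."""
    if model.coords is None or model.radii is None:
        raise ValueError("model must be placed")
    df = model.beads.copy()
    df["x"] = model.coords[:, 0]
    df["y"] = model.coords[:, 1]
    df["z"] = model.coords[:, 2]
    df["radius"] = model.radii
    df["shell"] = [assignment[int(b)] for b in df["bead_id"]]
    cols = ["chrom", "start", "end", "bead_id", "kind", "x", "y", "z", "radius", "shell"]
    df.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_model(
    path, nucleus_radius: float = 5.0, occupancy: float = 0.15
) -> tuple[BeadModel, dict[int, str]]:
    """Read a model table written by :func:`export_model`."""
    df = pd.read_csv(path, sep="\t")
    beads = df.loc[:, ["bead_id", "chrom", "start", "end", "kind"]].reset_index(drop=True)
    model = BeadModel(
        beads=beads,
        nucleus_radius=nucleus_radius,
        occupancy=occupancy,
        radii=df["radius"].to_numpy(),
        coords=df.loc[:, ["x", "y", "z"]].to_numpy(),
    )
    assignment = {int(b): s for b, s in zip(df["bead_id"], df["shell"])}
    return model, assignment
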