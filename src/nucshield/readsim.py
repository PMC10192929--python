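"""Nucleotide-frequency-matched read simulation ("expected" reads).

UV damage and repair reads are sequence-biased: they are drawn from
dipyrimidine-containing sites, so their per-position nucleotide profile
differs sharply from the genome background. To build an *expected* read
set — where reads would fall if only sequence content mattered — we sample
pseudo-reads from the reference genome (or from an input-DNA background
read set, which additionally carries any copy-number structure) and accept
them so that, per read length, the accepted reads' per-position nucleotide
frequencies match a target profile inferred from the real reads.

Acceptance combines two ratio terms in a closed feedback loop:

* target over *candidate* frequency (a running estimate of the proposal
  distribution), which performs the actual importance correction, and
* target over *emitted* frequency, a corrective term whose fixed point
  pins the output marginals to the target even where the proposal estimate
  is off or the envelope cap has bitten.

Both estimates are updated continually as reads are drawn, so the sampler
steers itself toward the target profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FreqProfile", "infer_freq_profile", "simulate_reads", "SimulationError", "profile_mad"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


class SimulationError(RuntimeError):
    """Raised when the target profile cannot be matched from the reference."""


@dataclass
class FreqProfile:
    """Per-length position x base (A,C,G,T) frequency matrices plus the
    read-length distribution. Every matrix row sums to 1, as does the
    length distribution."""

    matrices: dict[int, np.ndarray]
    length_probs: dict[int, float]

    def __post_init__(self) -> None:
        for L, mat in self.matrices.items():
            if mat.shape != (L, 4):
                raise ValueError(f"matrix for length {L} has shape {mat.shape}")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"length-{L} matrix rows must sum to 1")
        if abs(sum(self.length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("length distribution must sum to 1")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def infer_freq_profile(reads) -> FreqProfile:
    """Empirical per-position nucleotide frequencies per read length.

    ``reads`` is a sequence of strings or a DataFrame with a ``seq``
    column. Non-ACGT bases are excluded from their column's denominator.
    """
    seqs = list(reads["seq"]) if isinstance(reads, pd.DataFrame) else list(reads)
    if len(seqs) == 0:
        raise ValueError("cannot infer a profile from zero reads")
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    matrices: dict[int, np.ndarray] = {}
    for L, group in by_len.items():
        codes = np.stack([_encode(s) for s in group])
        counts = np.zeros((L, 4), dtype=float)
        for b in range(4):
            counts[:, b] = (codes == b).sum(axis=0)
        valid = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = counts / valid
        mat[valid[:, 0] == 0] = 0.25  # column of only ambiguous bases
        matrices[L] = mat
    n = len(seqs)
    length_probs = {L: len(g) / n for L, g in by_len.items()}
    return FreqProfile(matrices=matrices, length_probs=length_probs)


def profile_mad(target: np.ndarray, emitted: np.ndarray) -> float:
    """Mean absolute deviation between two position-by-base matrices."""
    return float(np.abs(target - emitted).mean())


def _freqs(counts: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    return (counts + alpha) / (counts.sum(axis=1, keepdims=True) + 4 * alpha)


def simulate_reads(
    reference: dict[str, str],
    profile: FreqProfile,
    n: int,
    seed: int = 0,
    background: pd.DataFrame | None = None,
    epsilon: float = 0.02,
    max_attempts: int = 200,
    batch_size: int = 8192,
) -> pd.DataFrame:
    """Sample ``n`` frequency-matched pseudo-reads from the reference.

    Candidate positions are uniform over the reference (or uniform over
    ``background`` read footprints when given, which preserves regional
    copy number); strand is uniform. Candidates are accepted by the
    feedback rule described in the module docstring. Returns a BED6-style
    frame with a ``seq`` column (read-orientation sequence, equal to the
    reference at the coordinates, reverse-complemented on minus).

    Raises :class:`SimulationError` when, for some read length, more than
    ``max_attempts`` candidates per requested read have been drawn without
    filling the quota.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    encoded = {c: _encode(s) for c, s in reference.items()}

    lengths = sorted(profile.length_probs)
    probs = np.array([profile.length_probs[L] for L in lengths], dtype=float)
    quotas = rng.multinomial(n, probs / probs.sum())

    if background is not None:
        bg = background.reset_index(drop=True)
        bg_len = (bg["end"] - bg["start"]).to_numpy()

    rows: list[tuple[str, int, int, str, str]] = []
    for L, quota in zip(lengths, quotas):
        if quota == 0:
            continue
        target = profile.matrices[L]
        cand_counts = np.zeros((L, 4), dtype=float)
        emit_counts = target * 50.0  # prior keeps early feedback neutral
        envelope = 1e-12
        accepted = 0
        drawn = 0
        if background is None:
            chrom_names = [c for c in reference if len(reference[c]) >= L]
            if not chrom_names:
                raise SimulationError(f"no reference sequence holds a {L}-mer")
            chrom_w = np.array([len(reference[c]) - L + 1 for c in chrom_names], dtype=float)
            chrom_w /= chrom_w.sum()
        else:
            pool = np.flatnonzero(bg_len >= L)
            if len(pool) == 0:
                raise SimulationError(f"no background read is {L} bp or longer")
        while accepted < quota:
            m = batch_size
            if background is None:
                which = rng.choice(len(chrom_names), size=m, p=chrom_w)
                cand_chrom = np.array(chrom_names, dtype=object)[which]
                limits = np.array([len(reference[c]) - L for c in cand_chrom])
                cand_start = rng.integers(0, limits + 1)
            else:
                ridx = pool[rng.integers(0, len(pool), size=m)]
                cand_chrom = bg["chrom"].to_numpy()[ridx]
                offs = rng.integers(0, bg_len[ridx] - L + 1)
                cand_start = bg["start"].to_numpy()[ridx] + offs
            cand_minus = rng.random(m) < 0.5

            codes = np.empty((m, L), dtype=np.uint8)
            for chrom in np.unique(cand_chrom):
                sel = cand_chrom == chrom
                pos = cand_start[sel, None] + np.arange(L)[None, :]
                codes[sel] = encoded[chrom][pos]
            valid = (codes < 4).all(axis=1)
            codes = codes[valid]
            cand_chrom, cand_start, cand_minus = (
                cand_chrom[valid],
                cand_start[valid],
                cand_minus[valid],
            )
            drawn += m
            if len(codes) == 0:
                _check_attempts(drawn, quota, max_attempts, L, target, emit_counts)
                continue
            codes[cand_minus] = 3 - codes[cand_minus][:, ::-1]

            cand_counts += np.stack(
                [(codes == b).sum(axis=0) for b in range(4)], axis=1
            ).astype(float)
            g_hat = _freqs(cand_counts)
            f_hat = _freqs(emit_counts, alpha=1e-9)
            pos_idx = np.arange(L)[None, :]
            prod = np.prod(target[pos_idx, codes] / g_hat[pos_idx, codes], axis=1)
            envelope = max(envelope, float(prod.max()))
            with np.errstate(divide="ignore", invalid="ignore"):
                fb = np.prod(target[pos_idx, codes] / f_hat[pos_idx, codes], axis=1)
            fb = np.clip(np.nan_to_num(fb, nan=0.0, posinf=5.0), 0.2, 5.0)
            p_accept = np.minimum(1.0, prod / envelope * fb)
            take = np.flatnonzero(rng.random(len(codes)) < p_accept)
            need = quota - accepted
            take = take[:need]
            for t in take:
                emit_counts[np.arange(L), codes[t]] += 1.0
                strand = "-" if cand_minus[t] else "+"
                seq = _BASES[codes[t]].tobytes().decode("ascii")
                rows.append((cand_chrom[t], int(cand_start[t]), int(cand_start[t]) + L, strand, seq))
            accepted += len(take)
            if accepted < quota:
                _check_attempts(drawn, quota, max_attempts, L, target, emit_counts)

        emitted = _freqs(emit_counts - target * 50.0, alpha=1e-9)
        mad = profile_mad(target, emitted)
        if quota >= 5000 and mad > epsilon:
            warnings.warn(
                f"length {L}: emitted frequencies deviate from target (MAD {mad:.4f})",
                stacklevel=2,
            )

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "seq"])
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(3, "name", [f"sim_{i}" for i in range(len(df))])
    df.insert(4, "score", 0)
    return df


def _check_attempts(drawn, quota, max_attempts, L, target, emit_counts) -> None:
    if drawn > max_attempts * quota:
        emitted = _freqs(emit_counts, alpha=1e-9)
        dev = np.abs(target - emitted).max(axis=1)
        worst = np.argsort(dev)[::-1][:3]
        detail = ", ".join(f"pos {int(p) + 1} (|Δ|={dev[p]:.3f})" for p in worst)
        raise SimulationError(
            f"length {L}: exceeded {max_attempts} attempts per read; "
            f"hardest positions: {detail}"
        )
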