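"""Generators: determinism, bounds, and recovery of planted structure."""

import numpy as np
import pandas as pd
import pytest

from nucshield import (
    GenomeSpec,
    RadialEffectSpec,
    dipyrimidine_sites,
    generate_domains,
    generate_edu_counts,
    generate_genes,
    generate_genome,
    generate_interactions,
    generate_reads,
    xr_length_distribution,
)


def tt_tc_density(seq: str) -> float:
    codes = np.frombuffer(seq.encode(), dtype="S1")
    hits = (codes[:-1] == b"T") & ((codes[1:] == b"T") | (codes[1:] == b"C"))
    return float(hits.mean())


class TestGenome:
    def test_lengths_and_determinism(self):
        spec = GenomeSpec({"chr1": 1000, "chr2": 500})
        g1 = generate_genome(spec, seed=7)
        g2 = generate_genome(spec, seed=7)
        assert len(g1["chr1"]) == 1000 and len(g1["chr2"]) == 500
        assert g1 == g2
        assert g1 != generate_genome(spec, seed=8)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec({"chr1": 0})

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GenomeSpec({"chr1": 100}, base_composition=(0.5, 0.5, 0.5, 0.5))

    def test_planted_dipyrimidine_gradient(self):
        # 3x 5'->3' multiplier: last-decile / first-decile TT+TC density
        # within 20% of 3 at Mb scale (analytic expectation ~2.64 for a
        # linear profile measured at decile midpoints)
        spec = GenomeSpec({"chr1": 1_000_000}, dipyrimidine_gradient={"chr1": 3.0})
        seq = generate_genome(spec, seed=7)["chr1"]
        decile = len(seq) // 10
        ratio = tt_tc_density(seq[9 * decile :]) / tt_tc_density(seq[:decile])
        assert ratio == pytest.approx(3.0, rel=0.20)

    def test_gradient_density_level_is_planted_rate(self):
        spec = GenomeSpec({"chr1": 500_000}, dipyrimidine_gradient={"chr1": 1.0})
        seq = generate_genome(spec, seed=3)["chr1"]
        assert tt_tc_density(seq) == pytest.approx(spec.dipyrimidine_rate, rel=0.05)


class TestDomainsAndGenes:
    def test_zero_domains_empty(self):
        assert len(generate_domains({"chr1": 10_000_000}, 0)) == 0

    def test_bounds_and_count(self):
        sizes = {f"chr{i}": 10_000_000 for i in range(1, 4)}
        doms = generate_domains(sizes, 50, (50_000, 200_000), seed=1)
        assert len(doms) == 50
        for _, r in doms.iterrows():
            assert 0 <= r.start < r.end <= sizes[r.chrom]

    def test_overlap_flag_produces_overlap(self):
        doms = generate_domains({"chr1": 10_000_000}, 10, (50_000, 100_000), seed=2,
                                allow_overlap=True)
        doms = doms.sort_values("start").reset_index(drop=True)
        overlaps = (doms["start"].to_numpy()[1:] < doms["end"].to_numpy()[:-1]).any()
        assert overlaps

    def test_infeasible_request_raises(self):
        with pytest.raises(ValueError):
            generate_domains({"chr1": 1_000_000}, 100, (50_000, 200_000), seed=0)

    def test_genes_within_bounds(self):
        sizes = {"chr1": 5_000_000}
        genes = generate_genes(sizes, 200, seed=4)
        assert len(genes) == 200
        assert (genes["start"] >= 0).all() and (genes["end"] <= 5_000_000).all()


class TestInteractions:
    def test_zero_pairs(self):
        assert generate_interactions(range(10), 0) == []

    def test_distinct_and_unordered(self):
        pairs = generate_interactions(range(30), 200, seed=5)
        assert len(pairs) == 200
        canon = {(min(a, b), max(a, b)) for a, b in pairs}
        assert len(canon) == 200
        assert all(a != b for a, b in pairs)

    def test_too_many_pairs_raises(self):
        with pytest.raises(ValueError):
            generate_interactions(range(5), 11)

    def test_central_excess(self):
        central = set(range(15))  # 105 distinct within-set pairs
        pairs = generate_interactions(range(100), 100, central_set=central,
                                      central_excess=0.8, seed=6)
        within = sum(1 for a, b in pairs if a in central and b in central)
        assert within >= 60


class TestReads:
    def test_effect_requires_shell_map(self, layered_model):
        model, _, _ = layered_model
        eff = RadialEffectSpec({"4-5": 2.0})
        with pytest.raises(ValueError):
            generate_reads(model.beads, "input", 100, effect=eff)

    def test_unknown_kind_rejected(self, layered_model):
        model, _, _ = layered_model
        with pytest.raises(ValueError):
            generate_reads(model.beads, "chipseq", 100)

    def test_uniform_counts_on_equal_beads(self):
        beads = pd.DataFrame(
            {"bead_id": [0, 1], "chrom": "chr1", "start": [0, 1_000_000],
             "end": [1_000_000, 2_000_000], "kind": "gap"}
        )
        reads = generate_reads(beads, "input", 10_000, seed=7)
        n0 = ((reads["start"] + reads["end"]) // 2 < 1_000_000).sum()
        # two-sample Poisson check: |n0 - n1| below 4 sigma of the difference
        assert abs(n0 - (10_000 - n0)) < 4 * np.sqrt(10_000)

    def test_planted_shell_multiplier_recovered(self, layered_model):
        model, assignment, _ = layered_model
        eff = RadialEffectSpec({"4-5": 2.0})
        reads = generate_reads(model.beads, "input", 200_000, seed=8,
                               effect=eff, shell_map=assignment)
        mid = (reads["start"] + reads["end"]) // 2
        starts = model.beads["start"].to_numpy()
        idx = np.searchsorted(starts, mid, side="right") - 1
        counts = np.bincount(idx, minlength=len(starts))
        per_kb = counts / (model.lengths_bp / 1e3)
        shells = np.array([assignment[int(b)] for b in model.beads["bead_id"]])
        ratio = per_kb[shells == "4-5"].mean() / per_kb[shells == "0-1"].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_damage_reads_pure_lesions(self, small_genome):
        genome, sizes = small_genome
        beads = pd.DataFrame(
            {"bead_id": [0], "chrom": "chr1", "start": [0], "end": [sizes["chr1"]],
             "kind": "gap"}
        )
        reads = generate_reads(beads, "damage", 2000, seed=9, genome=genome, purity=1.0)
        # lesion dinucleotide sits 2 nt upstream of the 5' read start
        plus, minus = dipyrimidine_sites(genome["chr1"])
        plus_set, minus_set = set(plus.tolist()), set(minus.tolist())
        for _, r in reads.iterrows():
            if r.strand == "+":
                assert r.start - 2 in plus_set
            else:
                assert r.end in minus_set

    def test_reads_within_bounds_and_stranded(self, small_genome):
        genome, sizes = small_genome
        beads = pd.DataFrame(
            {"bead_id": [0], "chrom": "chr1", "start": [0], "end": [sizes["chr1"]],
             "kind": "gap"}
        )
        for kind in ("damage", "repair", "input"):
            reads = generate_reads(beads, kind, 3000, seed=10, genome=genome)
            assert (reads["start"] >= 0).all()
            assert (reads["end"] <= sizes["chr1"]).all()
            assert reads["strand"].isin(["+", "-"]).all()

    def test_repair_lengths_follow_distribution(self, small_genome):
        genome, sizes = small_genome
        beads = pd.DataFrame(
            {"bead_id": [0], "chrom": "chr1", "start": [0], "end": [sizes["chr1"]],
             "kind": "gap"}
        )
        reads = generate_reads(beads, "repair", 5000, seed=11, genome=genome)
        lens = reads["end"] - reads["start"]
        assert lens.between(20, 30).all()
        assert lens.mode().iloc[0] == 26

    def test_determinism(self, layered_model):
        model, _, _ = layered_model
        a = generate_reads(model.beads, "input", 1000, seed=12)
        b = generate_reads(model.beads, "input", 1000, seed=12)
        pd.testing.assert_frame_equal(a, b)


class TestEduCounts:
    @staticmethod
    def _domains():
        return pd.DataFrame(
            {"chrom": "chr1", "start": [0, 2_000_000], "end": [1_000_000, 3_000_000],
             "label": ["early", "late"]}
        )

    def test_null_effect_balanced(self):
        counts = generate_edu_counts({"chr1": 4_000_000}, self._domains(),
                                     log2_effect=0.0, seed=13)
        r = np.log2((counts["early"] + 0.5) / (counts["late"] + 0.5))
        assert abs(r.mean()) < 0.1

    def test_strong_effect_signs_windows(self):
        counts = generate_edu_counts({"chr1": 4_000_000}, self._domains(),
                                     depth=100.0, log2_effect=2.0, seed=14)
        doms = self._domains()
        mid = (counts["start"] + counts["end"]) // 2
        in_early = (mid >= 0) & (mid < 1_000_000)
        in_late = (mid >= 2_000_000) & (mid < 3_000_000)
        r = np.log2((counts["early"] + 0.5) / (counts["late"] + 0.5))
        correct = (r[in_early] > 0).sum() + (r[in_late] < 0).sum()
        assert correct / (in_early.sum() + in_late.sum()) >= 0.90

    def test_partial_window_flagged(self):
        counts = generate_edu_counts({"chr1": 125_000}, self._domains().iloc[:0],
                                     window=50_000, seed=15)
        assert counts["partial"].tolist() == [False, False, True]
        assert counts["end"].iloc[-1] == 125_000

    def test_determinism(self):
        a = generate_edu_counts({"chr1": 1_000_000}, self._domains(), seed=16)
        b = generate_edu_counts({"chr1": 1_000_000}, self._domains(), seed=16)
        pd.testing.assert_frame_equal(a, b)


def test_xr_length_distribution_normalised():
    dist = xr_length_distribution()
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
    assert max(dist, key=dist.get) == 26
    assert min(dist) == 20 and max(dist) == 30
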