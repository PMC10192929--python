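"""Bead partitioning, volume scaling, loss, MC placement, shells, export."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_merge
from nucshield import (
    BeadModel,
    assign_shells,
    build_bead_partition,
    export_model,
    fit_model,
    load_model,
    loss,
    map_interactions_to_beads,
    optimize_model,
    place_on_radii,
    scale_bead_radii,
    shell_labels,
)


def make_model(beads, **kw):
    return BeadModel(beads=beads, radii=scale_bead_radii(beads), **kw)


class TestPartition:
    def test_no_domains_single_gap_bead(self):
        beads = build_bead_partition(pd.DataFrame(columns=["chrom", "start", "end"]),
                                     {"chr1": 10_000_000})
        assert len(beads) == 1
        row = beads.iloc[0]
        assert (row.start, row.end, row.kind) == (0, 10_000_000, "gap")

    def test_overlapping_domains_merged(self):
        doms = pd.DataFrame({"chrom": "chr1", "start": [0, 50_000], "end": [100_000, 150_000]})
        beads = build_bead_partition(doms, {"chr1": 200_000})
        assert [(r.start, r.end, r.kind) for r in beads.itertuples()] == [
            (0, 150_000, "domain"),
            (150_000, 200_000, "gap"),
        ]

    def test_abutting_domains_stay_separate(self):
        doms = pd.DataFrame({"chrom": "chr1", "start": [0, 100], "end": [100, 200]})
        beads = build_bead_partition(doms, {"chr1": 300})
        assert len(beads[beads.kind == "domain"]) == 2

    def test_domain_outside_chromosome_raises(self):
        doms = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [400]})
        with pytest.raises(ValueError):
            build_bead_partition(doms, {"chr1": 300})

    @given(
        st.lists(
            st.tuples(st.integers(0, 90), st.integers(1, 30)).map(
                lambda t: ("chr1", t[0], min(t[0] + t[1], 100))
            ),
            max_size=8,
        )
    )
    def test_tiling_invariant(self, raw):
        doms = pd.DataFrame(raw, columns=["chrom", "start", "end"])
        beads = build_bead_partition(doms, {"chr1": 100})
        # gap-free, overlap-free tiling of [0, 100)
        assert beads["start"].iloc[0] == 0 and beads["end"].iloc[-1] == 100
        assert (beads["start"].to_numpy()[1:] == beads["end"].to_numpy()[:-1]).all()
        # domain beads equal the brute-force strict-overlap merge
        got = {(r.chrom, r.start, r.end) for r in beads[beads.kind == "domain"].itertuples()}
        assert got == brute_force_merge([tuple(r) for r in raw], abutting=False)


class TestRadii:
    def test_two_bead_closed_form(self):
        beads = pd.DataFrame(
            {"bead_id": [0, 1], "chrom": "c", "start": [0, 1_000_000],
             "end": [1_000_000, 8_000_000], "kind": "gap"}
        )
        radii = scale_bead_radii(beads, nucleus_diameter_um=10.0, occupancy=0.15)
        vols = 4.0 / 3.0 * math.pi * radii**3
        assert vols[0] == pytest.approx(9.817, abs=1e-3)
        assert vols[1] == pytest.approx(68.72, abs=1e-2)
        assert radii[0] == pytest.approx(1.328, abs=1e-3)
        assert radii[1] == pytest.approx(2.540, abs=1e-3)

    def test_occupancy_exact_any_partition(self):
        rng = np.random.default_rng(0)
        edges = np.sort(rng.choice(np.arange(1, 10_000_000), size=9, replace=False))
        bounds = np.concatenate([[0], edges, [10_000_000]])
        beads = pd.DataFrame(
            {"bead_id": range(10), "chrom": "c", "start": bounds[:-1], "end": bounds[1:],
             "kind": "gap"}
        )
        radii = scale_bead_radii(beads)
        total = (4.0 / 3.0 * math.pi * radii**3).sum()
        nucleus = 4.0 / 3.0 * math.pi * 5.0**3
        assert total / nucleus == pytest.approx(0.15, rel=1e-9)

    def test_single_bead_closed_form(self):
        beads = pd.DataFrame({"bead_id": [0], "chrom": "c", "start": [0], "end": [100],
                              "kind": "gap"})
        r = scale_bead_radii(beads)[0]
        assert r == pytest.approx(0.15 ** (1 / 3) * 5.0, rel=1e-12)

    def test_bad_parameters_raise(self):
        beads = pd.DataFrame({"bead_id": [0], "chrom": "c", "start": [0], "end": [100],
                              "kind": "gap"})
        with pytest.raises(ValueError):
            scale_bead_radii(beads, occupancy=0.0)
        with pytest.raises(ValueError):
            scale_bead_radii(beads, nucleus_diameter_um=-1.0)


class TestLoss:
    @staticmethod
    def _two_bead_model(d: float):
        beads = pd.DataFrame(
            {"bead_id": [0, 1], "chrom": ["a", "b"], "start": [0, 0],
             "end": [100, 100], "kind": "gap"}
        )
        m = BeadModel(beads=beads, radii=np.array([1.0, 1.0]))
        m.coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        return m

    def test_satisfied_constraints_zero(self):
        m = self._two_bead_model(2.5)
        assert loss(m, []) == 0.0

    def test_touching_interaction_zero(self):
        m = self._two_bead_model(2.0)
        assert loss(m, [(0, 1)]) == 0.0

    def test_unit_gap_unit_loss(self):
        m = self._two_bead_model(3.0)  # d = r_i + r_j + 1
        assert loss(m, [(0, 1)]) == pytest.approx(1.0, rel=1e-12)

    def test_unplaced_raises(self):
        m = self._two_bead_model(2.0)
        m.coords = None
        with pytest.raises(ValueError):
            loss(m, [])


class TestOptimizer:
    def test_zero_interactions_zero_loss_stays(self):
        beads = pd.DataFrame(
            {"bead_id": [0, 1], "chrom": ["a", "b"], "start": [0, 0],
             "end": [100, 100], "kind": "gap"}
        )
        m = BeadModel(beads=beads, radii=np.array([0.5, 0.5]))
        m.coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        placed, trace = optimize_model(m, [], n_steps=500, t0=0.0, seed=1)
        assert trace[0] == 0.0 and trace[-1] == 0.0

    def test_zero_steps_returns_initial(self):
        beads = pd.DataFrame({"bead_id": [0], "chrom": "a", "start": [0], "end": [100],
                              "kind": "gap"})
        m = make_model(beads)
        placed, trace = optimize_model(m, [], n_steps=0, seed=2)
        assert len(trace) == 1 and placed.coords is not None

    def test_two_bead_toy_converges_to_touching(self):
        beads = pd.DataFrame(
            {"bead_id": [0, 1], "chrom": ["a", "b"], "start": [0, 0],
             "end": [1_000_000, 1_000_000], "kind": "gap"}
        )
        m = make_model(beads)
        placed, trace = optimize_model(m, [(0, 1)], n_steps=10_000, t0=0.0, seed=1)
        d = np.linalg.norm(placed.coords[0] - placed.coords[1])
        assert abs(d - placed.radii.sum()) <= 0.05
        assert (np.diff(trace) <= 1e-9).all()  # greedy: non-increasing

    def test_seed_reproducibility(self, layered_model):
        model, _, _ = layered_model
        a, _ = optimize_model(model, [(0, 5)], n_steps=2000, seed=3)
        b, _ = optimize_model(model, [(0, 5)], n_steps=2000, seed=3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_interacting_pairs_closer_on_50_bead_toy(self):
        from nucshield import generate_domains, generate_interactions

        sizes = {"chr1": 10_000_000}
        doms = generate_domains(sizes, 49, (50_000, 150_000), seed=2)
        beads = build_bead_partition(doms, sizes)
        model = make_model(beads)
        pairs = generate_interactions(beads["bead_id"], 40, seed=3)
        placed, trace = fit_model(model, pairs, n_steps=30_000, polish_steps=10_000, seed=4)
        inter = np.array(pairs)
        d_int = np.linalg.norm(
            placed.coords[inter[:, 0]] - placed.coords[inter[:, 1]], axis=1
        ).mean()
        rng = np.random.default_rng(0)
        pset = {tuple(sorted(p)) for p in pairs}
        d_rand = []
        while len(d_rand) < 200:
            a, b = rng.choice(len(beads), 2, replace=False)
            if tuple(sorted((a, b))) not in pset:
                d_rand.append(np.linalg.norm(placed.coords[a] - placed.coords[b]))
        assert d_int < np.mean(d_rand)
        # containment after optimization
        excess = np.maximum(
            0.0, np.linalg.norm(placed.coords, axis=1) + placed.radii - 5.0
        ).sum()
        assert excess <= 0.05


class TestShells:
    @staticmethod
    def _model_at(distances):
        n = len(distances)
        beads = pd.DataFrame(
            {"bead_id": range(n), "chrom": "c", "start": np.arange(n) * 10,
             "end": (np.arange(n) + 1) * 10, "kind": "gap"}
        )
        m = BeadModel(beads=beads, radii=np.full(n, 0.1))
        return place_on_radii(m, np.asarray(distances), seed=0)

    def test_center_distance_binning(self):
        m = self._model_at([2.4, 1.0, 0.0, 4.999])
        shells = assign_shells(m)
        assert shells[0] == "2-3"
        assert shells[1] == "1-2"  # half-open boundary
        assert shells[2] == "0-1"
        assert shells[3] == "4-5"

    def test_label_set(self):
        assert shell_labels(5.0, 1.0) == ["0-1", "1-2", "2-3", "3-4", "4-5"]

    def test_center_outside_nucleus_raises(self):
        m = self._model_at([5.2])
        with pytest.raises(ValueError):
            assign_shells(m)


class TestExport:
    def test_round_trip(self, tmp_path, layered_model):
        model, assignment, _ = layered_model
        path = tmp_path / "model.tsv"
        export_model(model, assignment, path)
        loaded, loaded_assignment = load_model(path)
        assert loaded.n_beads == model.n_beads
        assert loaded_assignment == assignment
        np.testing.assert_allclose(loaded.coords, model.coords, atol=1e-6)
        np.testing.assert_allclose(loaded.radii, model.radii, atol=1e-6)

    def test_row_count_matches_beads(self, tmp_path, layered_model):
        model, assignment, _ = layered_model
        path = tmp_path / "model.tsv"
        export_model(model, assignment, path)
        n_rows = len(path.read_text().strip().splitlines()) - 1  # minus header
        assert n_rows == model.n_beads


def test_interval_pair_mapping_by_midpoint():
    beads = pd.DataFrame(
        {"bead_id": [0, 1], "chrom": "chr1", "start": [0, 500], "end": [500, 1000],
         "kind": "gap"}
    )
    pairs = map_interactions_to_beads(
        [(("chr1", 0, 100), ("chr1", 600, 700))], beads
    )
    assert pairs == [(0, 1)]
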