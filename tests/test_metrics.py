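"""Graph-metric tests: parcel series, Fisher Z, within/between averaging,
participation coefficients over tie densities, spatial extent, QC table."""

import numpy as np
import pandas as pd
import pytest

from emaconn.bold import BOLDSimConfig, simulate_bold
from emaconn.mapping import (
    Parcellation,
    VertexAssignment,
    assign_vertices,
    parcellate,
    vertex_connectivity,
)
from emaconn.metrics import (
    ParcelConnectivity,
    fisher_z,
    metrics_table,
    parcel_connectivity,
    parcel_timeseries,
    participation_coefficients,
    spatial_extent,
    within_between,
)
from emaconn.surface import make_surface
from emaconn.templates import UNASSIGNED, make_templates
from emaconn.timeseries import VertexTimeSeries


def _parcellation(labels, vertex_sets, ids=("A", "B", "C")):
    return Parcellation(
        network_ids=ids,
        parcel_labels=list(labels),
        parcel_vertices=[np.asarray(v) for v in vertex_sets],
    )


class TestParcelTimeseries:
    def test_identical_vertices_give_member_series(self, rng):
        x = rng.standard_normal(60)
        ts = VertexTimeSeries(np.stack([x, x, x]))
        p = _parcellation([0], [[0, 1, 2]])
        out = parcel_timeseries(ts, p)
        np.testing.assert_allclose(out[0], x)

    def test_opposite_vertices_cancel(self, rng):
        x = rng.standard_normal(60)
        ts = VertexTimeSeries(np.stack([x, -x]))
        out = parcel_timeseries(ts, _parcellation([0], [[0, 1]]))
        np.testing.assert_allclose(out[0], 0.0, atol=1e-14)

    def test_matches_mean_oracle_with_censoring(self, rng):
        data = rng.standard_normal((10, 80))
        mask = rng.random(80) > 0.3
        ts = VertexTimeSeries(data, censor_mask=mask)
        sets = [[0, 1, 2], [3, 4], [5, 6, 7], [8, 9]]
        out = parcel_timeseries(ts, _parcellation([0, 1, 2, 0], sets))
        for k, verts in enumerate(sets):
            expected = data[np.asarray(verts)][:, mask].mean(axis=0)
            np.testing.assert_allclose(out[k], expected, atol=1e-12)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)

    @pytest.mark.parametrize("r", np.arange(0.1, 1.0, 0.1))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_unit_correlation_clipped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.2)


class TestWithinBetween:
    def _pc(self, z, labels, ids=("A", "B", "C")):
        z = np.asarray(z, dtype=float)
        np.fill_diagonal(z, 0.0)
        return ParcelConnectivity(z=z, labels=np.asarray(labels), network_ids=ids)

    def test_two_parcel_network(self):
        z = np.array([[0.0, 0.8], [0.8, 0.0]])
        within, _ = within_between(self._pc(z, [0, 0]))
        assert within["A"] == pytest.approx(0.8)

    def test_single_parcel_network_missing(self):
        z = np.array([[0.0, 0.3], [0.3, 0.0]])
        within, between = within_between(self._pc(z, [0, 1]))
        assert np.isnan(within["A"]) and np.isnan(within["B"])
        assert between[("A", "B")] == pytest.approx(0.3)

    def test_absent_network_pair_missing(self):
        z = np.array([[0.0, 0.3], [0.3, 0.0]])
        _, between = within_between(self._pc(z, [0, 0]))
        assert np.isnan(between[("A", "B")])

    def test_matches_pair_enumeration_oracle(self, rng):
        n = 10
        z = rng.standard_normal((n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        labels = rng.integers(0, 3, n)
        pc = self._pc(z, labels)
        within, between = within_between(pc)
        ids = pc.network_ids
        for a in range(3):
            vals = [z[i, j] for i in range(n) for j in range(i + 1, n)
                    if labels[i] == a and labels[j] == a]
            if len(vals) >= 1:
                assert within[ids[a]] == pytest.approx(np.mean(vals), abs=1e-12)
            for b in range(a + 1, 3):
                vals = [z[i, j] for i in range(n) for j in range(n)
                        if labels[i] == a and labels[j] == b]
                if vals:
                    assert between[(ids[a], ids[b])] == pytest.approx(
                        np.mean(vals), abs=1e-12
                    )

    def test_invariant_to_parcel_ordering(self, rng):
        n = 8
        z = rng.standard_normal((n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        labels = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        w1, b1 = within_between(self._pc(z.copy(), labels))
        perm = np.random.default_rng(5).permutation(n)
        w2, b2 = within_between(self._pc(z[np.ix_(perm, perm)], labels[perm]))
        for k in w1:
            assert w1[k] == pytest.approx(w2[k], abs=1e-12, nan_ok=True)
        for k in b1:
            assert b1[k] == pytest.approx(b2[k], abs=1e-12, nan_ok=True)


def _brute_force_pc(z, labels, K, density):
    """Direct Sigma(k_is/k_i)^2 summation on an explicitly built graph."""
    n = z.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    keyed = sorted(range(len(pairs)), key=lambda idx: (-z[pairs[idx]], idx))
    m = int(np.floor(density * len(pairs)))
    edges = [pairs[idx] for idx in keyed[:m]]
    pcs = np.zeros(n)
    for i in range(n):
        nbrs = [j for (a, j) in edges if a == i] + [a for (a, j) in edges if j == i]
        k_i = len(nbrs)
        if k_i == 0:
            continue
        s = 0.0
        for net in range(K):
            k_is = sum(1 for j in nbrs if labels[j] == net)
            s += (k_is / k_i) ** 2
        pcs[i] = 1.0 - s
    return pcs


class TestParticipation:
    def _pc_mat(self, z, labels, ids):
        z = np.asarray(z, dtype=float)
        np.fill_diagonal(z, 0.0)
        return ParcelConnectivity(z=z, labels=np.asarray(labels), network_ids=ids)

    def test_all_internal_edges_give_zero(self):
        # two clusters; strong edges only inside each network
        z = np.full((6, 6), -5.0)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        z[i, j] = 1.0
        labels = np.array([0, 0, 0, 1, 1, 1])
        out = participation_coefficients(
            self._pc_mat(z, labels, ("A", "B")),
            densities=np.array([0.4]), avg_over=1,
        )
        assert out["A"] == pytest.approx(0.0)
        assert out["B"] == pytest.approx(0.0)

    def test_four_way_spread_closed_form(self):
        # hub node 0 with exactly one edge into each of 4 networks:
        # PC = 1 - 4 * (1/4)^2 = 0.75
        n = 9
        z = np.full((n, n), -9.0)
        hubs = [1, 3, 5, 7]
        for rank, j in enumerate(hubs):
            z[0, j] = z[j, 0] = 10.0 - rank
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 3, 3])
        zb = z.copy()
        np.fill_diagonal(zb, 0.0)
        out_nodes = _brute_force_pc(zb, labels, 4, 4 / 36)  # 36 pairs, keep 4
        assert out_nodes[0] == pytest.approx(0.75)
        got = participation_coefficients(
            self._pc_mat(z, labels, ("A", "B", "C", "D")),
            densities=np.array([4 / 36]), avg_over=1,
        )
        # network A holds the hub and two isolated parcels (PC 0)
        assert got["A"] == pytest.approx(0.75 / 3)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(8):
            n = int(rng.integers(8, 21))
            z = rng.standard_normal((n, n))
            z = (z + z.T) / 2
            np.fill_diagonal(z, 0.0)
            K = int(rng.integers(2, 5))
            labels = rng.integers(0, K, n)
            density = float(rng.choice([0.1, 0.2, 0.3]))
            ids = tuple(f"N{k}" for k in range(K))
            got = participation_coefficients(
                self._pc_mat(z, labels, ids),
                densities=np.array([density]), avg_over=1,
            )
            node_pcs = _brute_force_pc(z, labels, K, density)
            for k, name in enumerate(ids):
                idx = np.flatnonzero(labels == k)
                if idx.size:
                    assert got[name] == pytest.approx(
                        node_pcs[idx].mean(), abs=1e-12
                    )

    def test_pc_bounded_and_label_permutation_invariant(self, rng):
        n = 15
        z = rng.standard_normal((n, n))
        z = (z + z.T) / 2
        labels = rng.integers(0, 4, n)
        ids = ("A", "B", "C", "D")
        got = participation_coefficients(self._pc_mat(z, labels, ids))
        for name, v in got.items():
            if not np.isnan(v):
                assert 0.0 <= v <= 1.0 - 1.0 / 4 + 1e-12
        # relabeling networks permutes the outputs identically
        perm = np.array([2, 3, 1, 0])
        got2 = participation_coefficients(
            self._pc_mat(z, perm[labels], ids)
        )
        for k, name in enumerate(ids):
            assert got2[ids[perm[k]]] == pytest.approx(got[name], abs=1e-12,
                                                       nan_ok=True)

    def test_degree_monotone_in_density(self, rng):
        from emaconn.metrics import _binary_graph_at_density

        n = 12
        z = rng.standard_normal((n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        prev = np.zeros(n)
        for d in np.arange(0.05, 1.0, 0.05):
            rows, cols = _binary_graph_at_density(z, d)
            deg = np.bincount(np.concatenate([rows, cols]), minlength=n)
            assert (deg >= prev).all()
            prev = deg

    def test_single_parcel_rejected(self):
        pc = ParcelConnectivity(z=np.zeros((1, 1)), labels=np.array([0]),
                                network_ids=("A", "B"))
        with pytest.raises(ValueError):
            participation_coefficients(pc)


class TestSpatialExtent:
    def test_all_vertices_one_network(self):
        a = VertexAssignment(
            labels=np.zeros(1600, dtype=np.int64),
            dice=np.full(1600, 0.5),
            network_ids=("A", "B", "C"),
        )
        assert spatial_extent(a) == {"A": 1600, "B": 0, "C": 0}

    def test_counts_conserve_vertices(self, rng):
        labels = rng.integers(-1, 3, 500).astype(np.int64)
        a = VertexAssignment(
            labels=labels,
            dice=np.where(labels == UNASSIGNED, 0.0, 0.5),
            network_ids=("A", "B", "C"),
        )
        ext = spatial_extent(a)
        assert sum(ext.values()) + int((labels == UNASSIGNED).sum()) == 500

    def test_planted_partition_counts_recovered(self):
        surface = make_surface(20, 20, 1.0)
        templates, truth = make_templates(surface, K=4, seed=7)
        cfg = BOLDSimConfig(frames_per_run=1500, n_runs=1, within_corr=0.999,
                            between_corr=0.0, seed=1)
        ts, _ = simulate_bold(surface, truth, cfg)
        assignment = assign_vertices(vertex_connectivity(ts), templates)
        ext = spatial_extent(assignment)
        for k, name in enumerate(templates.network_ids):
            assert ext[name] == int((truth == k).sum())


@pytest.fixture(scope="module")
def mapped_cohort():
    surface = make_surface(12, 12, 4.0)
    templates, truth = make_templates(surface, K=8, seed=3)
    out = {}
    for i, seed in enumerate([11, 12, 13]):
        frames = 40 if i == 2 else 500  # participant 2 fails frame QC
        cfg = BOLDSimConfig(frames_per_run=frames, n_runs=1,
                            within_corr=0.6, seed=seed)
        ts, _ = simulate_bold(surface, truth, cfg)
        assignment = assign_vertices(vertex_connectivity(ts), templates)
        out[f"P{i}"] = (ts, assignment, parcellate(assignment, surface))
    return out


class TestMetricsTable:
    def test_column_counts_match_eight_network_design(self, mapped_cohort):
        table, qc = metrics_table(mapped_cohort, min_frames=375)
        within_cols = [c for c in table.columns if c.startswith("within_")]
        between_cols = [c for c in table.columns if c.startswith("between_")]
        pc_cols = [c for c in table.columns if c.startswith("pc_")]
        extent_cols = [c for c in table.columns if c.startswith("extent_")]
        assert len(within_cols) == 8
        assert len(between_cols) == 28  # all unordered network pairs C(8,2)
        assert len(pc_cols) == 8
        assert len(extent_cols) == 8

    def test_frame_qc_exclusion_reported(self, mapped_cohort):
        table, qc = metrics_table(mapped_cohort, min_frames=375)
        assert qc["included"] == 2
        assert [e["participant_id"] for e in qc["excluded"]] == ["P2"]
        assert "P2" not in set(table["participant_id"])

    def test_within_exceeds_between_on_block_structure(self):
        # vertex-level within/between separation on planted structure
        surface = make_surface(10, 10, 1.0)
        templates, truth = make_templates(surface, K=3, seed=5)
        cfg = BOLDSimConfig(frames_per_run=2000, n_runs=1, within_corr=0.5,
                            between_corr=0.0, seed=9)
        ts, _ = simulate_bold(surface, truth, cfg)
        pvert = Parcellation(
            network_ids=tuple(templates.network_ids),
            parcel_labels=[int(l) for l in truth],
            parcel_vertices=[np.array([v]) for v in range(surface.n_vertices)],
        )
        pts = parcel_timeseries(ts, pvert)
        pc_mat = parcel_connectivity(pts, pvert)
        within, between = within_between(pc_mat)
        assert min(within.values()) > max(between.values())
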