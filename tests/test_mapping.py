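"""Template-matching tests: cleaning, connectivity, binarization, Dice,
assignment, patch removal, parcellation — each against an independent oracle
where the operation is more than bookkeeping."""

import numpy as np
import pytest

from emaconn.bold import BOLDSimConfig, simulate_bold
from emaconn.mapping import (
    DenseConnectivity,
    assign_vertices,
    binarize_top_fraction,
    clean_timeseries,
    dice,
    parcellate,
    qc_retained_frames,
    remove_small_patches,
    vertex_connectivity,
)
from emaconn.surface import make_surface
from emaconn.templates import UNASSIGNED, NetworkTemplateSet, make_templates
from emaconn.timeseries import VertexTimeSeries


class TestCleaning:
    def test_constant_series_zeroed(self):
        ts = VertexTimeSeries(np.full((3, 200), 7.0))
        out = clean_timeseries(ts)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_nuisance_regressor_removes_matching_vertex(self, rng):
        data = rng.standard_normal((4, 300))
        ts = VertexTimeSeries(data.copy())
        out = clean_timeseries(ts, nuisance=data[2])
        # residual variance of the vertex equal to the regressor is ~0
        # relative to its input variance (bandpass acts on a zero series)
        assert out.data[2].var() <= 1e-10 * data[2].var()

    def test_bandpass_attenuates_out_of_band_sinusoid(self):
        # 0.2 Hz is above the 0.1 Hz cutoff at TR = 0.8 s
        t = np.arange(1200) * 0.8
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = clean_timeseries(VertexTimeSeries(sig[None, :]))
        # spectral oracle: compare total power via the periodogram
        power_in = np.abs(np.fft.rfft(sig)) ** 2
        power_out = np.abs(np.fft.rfft(out.data[0])) ** 2
        assert power_out.sum() < 0.10 * power_in.sum()

    def test_in_band_sinusoid_survives(self):
        t = np.arange(1200) * 0.8
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = clean_timeseries(VertexTimeSeries(sig[None, :]))
        assert out.data[0].var() > 0.5 * sig.var()

    def test_censored_frames_excluded_from_fit(self, rng):
        # a huge spike confined to censored frames must not tilt the fit
        data = rng.standard_normal((2, 400))
        mask = np.ones(400, dtype=bool)
        mask[100:110] = False
        spiked = data.copy()
        spiked[:, 100:110] += 1e6
        out_clean = clean_timeseries(VertexTimeSeries(data, censor_mask=mask))
        out_spiked = clean_timeseries(VertexTimeSeries(spiked, censor_mask=mask))
        keep = mask
        assert np.allclose(
            out_clean.data[:, keep], out_spiked.data[:, keep], atol=1e-3
        )

    def test_band_outside_nyquist_rejected(self):
        ts = VertexTimeSeries(np.random.default_rng(0).standard_normal((2, 100)))
        with pytest.raises(ValueError):
            clean_timeseries(ts, band=(0.01, 0.7))

    def test_constant_nuisance_dropped_with_warning(self, rng):
        ts = VertexTimeSeries(rng.standard_normal((2, 100)))
        with pytest.warns(UserWarning, match="constant"):
            clean_timeseries(ts, nuisance=np.ones(100))


class TestFrameQC:
    @pytest.mark.parametrize(
        "retained,expected", [(375, True), (374, False), (920, True), (0, False)]
    )
    def test_minimum_frame_rule(self, retained, expected):
        mask = np.zeros(920, dtype=bool)
        mask[:retained] = True
        assert qc_retained_frames(mask) is expected


class TestConnectivity:
    def test_identical_vertices_correlate_fully(self, rng):
        x = rng.standard_normal(100)
        ts = VertexTimeSeries(np.stack([x, x, -x]))
        conn = vertex_connectivity(ts)
        assert conn.matrix[0, 1] == pytest.approx(1.0)
        assert conn.matrix[0, 2] == pytest.approx(-1.0)

    def test_matches_two_pass_pearson_oracle(self, rng):
        data = rng.standard_normal((5, 100))
        mask = rng.random(100) > 0.2
        conn = vertex_connectivity(VertexTimeSeries(data, censor_mask=mask))
        kept = data[:, mask]
        for i in range(5):
            for j in range(5):
                xi, xj = kept[i] - kept[i].mean(), kept[j] - kept[j].mean()
                r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert conn.matrix[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_vertex_flagged(self, rng):
        data = rng.standard_normal((3, 50))
        data[1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            conn = vertex_connectivity(VertexTimeSeries(data))
        assert not conn.valid[1]
        assert np.isnan(conn.matrix[1]).all()
        assert conn.valid[[0, 2]].all()

    def test_too_few_retained_frames_rejected(self):
        ts = VertexTimeSeries(
            np.zeros((2, 10)), censor_mask=np.arange(10) < 1
        )
        with pytest.raises(ValueError):
            vertex_connectivity(ts)


class TestBinarize:
    def test_exact_count_at_five_percent(self, rng):
        values = rng.permutation(100).astype(float)  # 101-vertex surface row
        out = binarize_top_fraction(values, 0.05)
        assert out.sum() == 5
        assert set(np.flatnonzero(out)) == set(np.argsort(values)[-5:])

    def test_all_equal_row_takes_lowest_indices(self):
        with pytest.warns(UserWarning, match="tie"):
            out = binarize_top_fraction(np.ones(100), 0.05)
        assert np.array_equal(np.flatnonzero(out), np.arange(5))

    def test_single_connection_on_small_surface(self, rng):
        values = rng.standard_normal(20)  # 21-vertex surface
        out = binarize_top_fraction(values, 0.05)
        assert out.sum() == 1
        assert out[np.argmax(values)]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            binarize_top_fraction(np.ones(10), 0.05)


class TestDice:
    def test_identical_maps(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        assert dice(a, a) == 1.0

    def test_disjoint_maps(self):
        assert dice(np.array([1, 0, 0]), np.array([0, 1, 1])) == 0.0

    def test_partial_overlap_closed_form(self):
        a = np.zeros(20, dtype=bool)
        b = np.zeros(20, dtype=bool)
        a[:4] = True
        b[1:7] = True  # |a|=4, |b|=6, |a & b|=3
        assert dice(a, b) == pytest.approx(0.6)

    def test_both_empty_defined_as_zero(self):
        assert dice(np.zeros(5, dtype=bool), np.zeros(5, dtype=bool)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros(4, dtype=bool), np.zeros(5, dtype=bool))


def _brute_force_assign(conn_matrix, templates, fraction):
    """Exhaustive per-vertex recomputation: binarize each row independently
    and tabulate every Dice coefficient."""
    n = conn_matrix.shape[0]
    labels = np.full(n, UNASSIGNED)
    dices = np.zeros(n)
    for v in range(n):
        row = np.delete(conn_matrix[v], v)
        others = np.delete(np.arange(n), v)
        m = int(np.floor(fraction * (n - 1)))
        order = sorted(range(n - 1), key=lambda i: (-row[i], i))
        binmap = np.zeros(n, dtype=bool)
        binmap[others[order[:m]]] = True
        best, best_d = UNASSIGNED, 0.0
        for k in range(templates.maps.shape[0]):
            d = dice(binmap, templates.maps[k])
            if d > best_d:
                best, best_d = k, d
        labels[v] = best
        dices[v] = best_d
    return labels, dices


class TestAssignment:
    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(25, 51))
            rows = 5
            cols = n // rows + (n % rows > 0)
            surface = make_surface(5, max(cols, 3), 1.0)
            n = surface.n_vertices
            templates, _ = make_templates(surface, K=3, seed=trial)
            raw = rng.standard_normal((n, 40))
            mat = np.corrcoef(raw)
            conn = DenseConnectivity(matrix=mat, valid=np.ones(n, dtype=bool))
            got = assign_vertices(conn, templates, fraction=0.2)
            labels, dices = _brute_force_assign(mat, templates, 0.2)
            assert np.array_equal(got.labels, labels)
            np.testing.assert_allclose(got.dice, dices, atol=1e-12)

    def test_recovers_planted_partition(self):
        surface = make_surface(20, 20, 1.0)
        templates, truth = make_templates(surface, K=4, seed=2)
        cfg = BOLDSimConfig(frames_per_run=2000, n_runs=1, within_corr=0.9,
                            between_corr=0.0, seed=3)
        ts, _ = simulate_bold(surface, truth, cfg)
        conn = vertex_connectivity(ts)
        got = assign_vertices(conn, templates)
        assert (got.labels == truth).mean() >= 0.99

    def test_exact_template_match_scores_dice_one(self):
        surface = make_surface(5, 8, 1.0)  # 40 vertices; top 10% -> 3 entries
        n = surface.n_vertices
        maps = np.zeros((2, n), dtype=bool)
        maps[0, [1, 2, 3]] = True
        maps[1, [10, 11, 12, 13]] = True
        templates = NetworkTemplateSet(("A", "B"), maps)
        mat = np.full((n, n), -0.9)
        mat[0, [1, 2, 3]] = mat[[1, 2, 3], 0] = 0.9
        np.fill_diagonal(mat, 1.0)
        conn = DenseConnectivity(matrix=mat, valid=np.ones(n, dtype=bool))
        got = assign_vertices(conn, templates, fraction=0.08)  # floor(0.08*39) = 3
        assert got.labels[0] == 0
        assert got.dice[0] == pytest.approx(1.0)

    def test_vertex_matching_no_template_unassigned(self, rng):
        surface = make_surface(5, 8, 1.0)
        n = surface.n_vertices
        maps = np.zeros((2, n), dtype=bool)
        maps[0, [20, 21]] = True
        maps[1, [30, 31]] = True
        templates = NetworkTemplateSet(("A", "B"), maps)
        mat = np.full((n, n), 0.0)
        # vertex 0 connects strongly only to vertices outside both templates
        mat[0, [1, 2]] = mat[[1, 2], 0] = 0.9
        np.fill_diagonal(mat, 1.0)
        conn = DenseConnectivity(matrix=mat, valid=np.ones(n, dtype=bool))
        got = assign_vertices(conn, templates, fraction=0.06)  # 2 entries
        assert got.labels[0] == UNASSIGNED
        assert got.dice[0] == 0.0


class TestPatchRemoval:
    def _assignment(self, labels, network_ids=("A", "B")):
        from emaconn.mapping import VertexAssignment

        labels = np.asarray(labels)
        return VertexAssignment(
            labels=labels,
            dice=np.where(labels == UNASSIGNED, 0.0, 0.5),
            network_ids=network_ids,
        )

    def test_small_patch_removed(self):
        surface = make_surface(4, 4, 1.0)
        labels = np.zeros(16, dtype=np.int64)
        labels[[0, 1, 2]] = 1  # 3-vertex patch of B, area 3 mm^2
        out = remove_small_patches(self._assignment(labels), surface, min_area=5.0)
        assert (out.labels[[0, 1, 2]] == UNASSIGNED).all()
        assert (out.labels[3:] == 0).all()

    def test_exact_threshold_area_retained(self):
        surface = make_surface(10, 10, 1.0)
        labels = np.zeros(100, dtype=np.int64)
        labels[:30] = 1  # exactly 30 mm^2: "less than" is strict
        out = remove_small_patches(self._assignment(labels), surface, min_area=30.0)
        assert (out.labels[:30] == 1).all()

    def test_identity_when_all_patches_large(self, small_surface, small_templates):
        # every patch of the fixture covers >= one 4 mm^2 vertex, so a
        # 4 mm^2 floor leaves the assignment untouched
        templates, truth = small_templates
        a = self._assignment(truth, tuple(templates.network_ids))
        out = remove_small_patches(a, small_surface, min_area=4.0)
        assert np.array_equal(out.labels, a.labels)

    def test_area_scales_with_vertex_area(self):
        # same 3-vertex patch survives when each vertex covers 15 mm^2
        surface = make_surface(4, 4, 15.0)
        labels = np.zeros(16, dtype=np.int64)
        labels[[0, 1, 2]] = 1
        out = remove_small_patches(self._assignment(labels), surface, min_area=30.0)
        assert (out.labels[[0, 1, 2]] == 1).all()


def _flood_fill_components(labels, surface):
    """Oracle: enumerate same-label components by explicit flood fill."""
    seen = set()
    comps = []
    for start in range(surface.n_vertices):
        if start in seen or labels[start] == UNASSIGNED:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            for w in surface.neighbors(v):
                if labels[w] == labels[start] and w not in comp:
                    stack.append(int(w))
        seen |= comp
        comps.append((labels[start], frozenset(comp)))
    return comps


class TestParcellation:
    def _assignment(self, labels, ids=("A", "B")):
        from emaconn.mapping import VertexAssignment

        labels = np.asarray(labels)
        return VertexAssignment(
            labels=labels,
            dice=np.where(labels == UNASSIGNED, 0.0, 0.5),
            network_ids=ids,
        )

    def test_two_islands_one_label(self):
        surface = make_surface(3, 7, 1.0)
        labels = np.zeros(21, dtype=np.int64)
        labels[[0, 1]] = 1
        labels[[19, 20]] = 1
        p = parcellate(self._assignment(labels), surface)
        b_parcels = [v for l, v in zip(p.parcel_labels, p.parcel_vertices) if l == 1]
        assert len(b_parcels) == 2

    def test_single_connected_label_single_parcel(self, small_surface):
        labels = np.zeros(small_surface.n_vertices, dtype=np.int64)
        p = parcellate(self._assignment(labels), small_surface)
        assert p.n_parcels == 1
        assert len(p.parcel_vertices[0]) == small_surface.n_vertices

    def test_checkerboard_matches_flood_fill_oracle(self):
        surface = make_surface(6, 6, 1.0)
        r, c = np.divmod(np.arange(36), 6)
        labels = ((r + c) % 2).astype(np.int64)
        p = parcellate(self._assignment(labels), surface)
        assert p.n_parcels == 36  # every vertex isolated on 4-neighborhood
        oracle = _flood_fill_components(labels, surface)
        got = {(l, frozenset(map(int, v)))
               for l, v in zip(p.parcel_labels, p.parcel_vertices)}
        assert got == {(int(l), v) for l, v in oracle}

    def test_unassigned_excluded_and_partition(self, small_surface, small_templates):
        templates, truth = small_templates
        labels = truth.copy()
        labels[:10] = UNASSIGNED
        p = parcellate(self._assignment(labels, tuple(templates.network_ids)),
                       small_surface)
        all_verts = np.concatenate(p.parcel_vertices)
        assert len(all_verts) == len(set(all_verts))  # disjoint
        assert set(all_verts) == set(np.flatnonzero(labels != UNASSIGNED))

    def test_idempotent(self, small_surface, small_templates):
        templates, truth = small_templates
        a = self._assignment(truth, tuple(templates.network_ids))
        p1 = parcellate(a, small_surface)
        p2 = parcellate(a, small_surface)
        assert p1.parcel_labels == p2.parcel_labels
        for v1, v2 in zip(p1.parcel_vertices, p2.parcel_vertices):
            assert np.array_equal(v1, v2)

    def test_empty_assignment_warns(self, small_surface):
        labels = np.full(small_surface.n_vertices, UNASSIGNED, dtype=np.int64)
        with pytest.warns(UserWarning, match="no labeled"):
            p = parcellate(self._assignment(labels), small_surface)
        assert p.n_parcels == 0
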