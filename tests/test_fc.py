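"""Functional connectivity: Fisher z, ROI extraction, matrices, intra-node
strength, group averaging — all checked against brute-force oracles."""

import numpy as np
import pytest

from taumri.fc import (ConnMatrix, TimeSeriesMatrix, connectivity_matrix,
                       extract_roi_timeseries, fisher_z, group_average_matrix,
                       intra_node_strength, merge_hemispheres, node_strength_vector)
from taumri.io import Bold4D, VolumeGeometry
from taumri.synthetic import make_block_atlas


def _bold_on(atlas, fill):
    """Build a Bold4D whose voxel series are given by ``fill(i, j, k)``."""
    dims = atlas.geometry.dims
    n = len(fill(0, 0, 0))
    data = np.zeros((*dims, n))
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                data[i, j, k] = fill(i, j, k)
    return Bold4D(atlas.geometry, data, tr=2.84)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    @pytest.mark.parametrize("r", [0.5, -0.5])
    def test_matches_independent_log_formula(self, r):
        # atanh(r) = 0.5 * ln((1+r)/(1-r)), evaluated independently
        expected = 0.5 * np.log((1 + r) / (1 - r))
        assert fisher_z(r) == pytest.approx(expected, abs=1e-12)
        assert abs(fisher_z(0.5)) == pytest.approx(0.549306, abs=1e-6)

    def test_degenerate_correlations_clipped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == -fisher_z(-1.0)

    def test_monotone_and_odd(self):
        r = np.linspace(-0.95, 0.95, 41)
        z = fisher_z(r)
        assert np.all(np.diff(z) > 0)
        assert np.allclose(z, -fisher_z(-r))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(np.nan)


class TestExtractTimeseries:
    def test_two_voxel_mean(self):
        atlas = make_block_atlas(1, roi_shape=(2, 1, 1), layout=(1, 1, 1), gap=1)
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([5.0, 6.0, 10.0])
        series = {(1, 1, 1): a, (2, 1, 1): b}
        bold = _bold_on(atlas, lambda i, j, k: series.get((i, j, k), np.zeros(3)))
        ts = extract_roi_timeseries(bold, atlas)
        assert np.allclose(ts.data[0], (a + b) / 2)

    def test_matches_bruteforce_average(self):
        rng = np.random.default_rng(0)
        atlas = make_block_atlas(4, roi_shape=(2, 2, 1))
        geom = atlas.geometry
        data = rng.standard_normal((*geom.dims, 20))
        bold = Bold4D(geom, data, tr=2.84)
        ts = extract_roi_timeseries(bold, atlas)
        for row, lab in enumerate(atlas.roi_table.index):
            acc = np.zeros(20)
            cnt = 0
            for idx in np.argwhere(atlas.labels == lab):
                acc += data[tuple(idx)]
                cnt += 1
            assert np.allclose(ts.data[row], acc / cnt, atol=1e-12)

    def test_geometry_mismatch_rejected(self):
        atlas = make_block_atlas(2)
        other = VolumeGeometry.from_voxel_size((4, 4, 4), (0.2, 0.2, 0.2))
        bold = Bold4D(other, np.zeros((4, 4, 4, 5)), tr=2.84)
        with pytest.raises(ValueError, match="geometry"):
            extract_roi_timeseries(bold, atlas)


class TestConnectivityMatrix:
    def test_matches_bruteforce_pearson_atanh(self):
        rng = np.random.default_rng(1)
        ts = TimeSeriesMatrix([f"r{i}" for i in range(5)], rng.standard_normal((5, 30)))
        conn = connectivity_matrix(ts)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert np.isnan(conn.z[i, j])
                    continue
                x, y = ts.data[i], ts.data[j]
                r = (np.sum((x - x.mean()) * (y - y.mean()))
                     / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
                assert conn.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_identical_rows_clipped_and_flagged(self):
        base = np.sin(np.arange(20))
        ts = TimeSeriesMatrix(["a", "b"], np.vstack([base, base]))
        conn = connectivity_matrix(ts)
        assert np.isfinite(conn.z[0, 1])
        assert conn.metadata["n_clipped_edges"] == 1
        anti = connectivity_matrix(TimeSeriesMatrix(["a", "b"], np.vstack([base, -base])))
        assert anti.z[0, 1] == pytest.approx(-conn.z[0, 1])

    def test_zero_variance_row_named_in_error(self):
        ts = TimeSeriesMatrix(["good", "flat"],
                              np.vstack([np.sin(np.arange(10)), np.ones(10)]))
        with pytest.raises(ValueError, match="flat"):
            connectivity_matrix(ts)

    def test_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 40))
        base = connectivity_matrix(TimeSeriesMatrix(list("abcd"), data))
        # positive scales: negative ones would flip correlation signs
        scaled = data * np.array([2.0, 3.0, 0.5, 10.0])[:, None] + \
            np.array([1.0, -5.0, 0.0, 2.0])[:, None]
        other = connectivity_matrix(TimeSeriesMatrix(list("abcd"), scaled))
        assert np.allclose(base.z, other.z, equal_nan=True, atol=1e-10)


class TestIntraNodeStrength:
    def test_three_voxel_hand_computation(self):
        atlas = make_block_atlas(1, roi_shape=(3, 1, 1), layout=(1, 1, 1), gap=1)
        rng = np.random.default_rng(3)
        series = {(1, 1, 1): rng.standard_normal(30),
                  (2, 1, 1): rng.standard_normal(30),
                  (3, 1, 1): rng.standard_normal(30)}
        bold = _bold_on(atlas, lambda i, j, k: series.get((i, j, k), np.zeros(30)))
        strength, n_excl = intra_node_strength(bold, atlas, "roi1")
        vals = list(series.values())
        pair_z = [np.arctanh(np.corrcoef(vals[a], vals[b])[0, 1])
                  for a, b in [(0, 1), (0, 2), (1, 2)]]
        assert strength == pytest.approx(np.mean(pair_z), abs=1e-12)
        assert n_excl == 0

    def test_shared_signal_with_jitter_is_strong(self):
        atlas = make_block_atlas(1, roi_shape=(3, 3, 2), layout=(1, 1, 1))
        rng = np.random.default_rng(4)
        shared = rng.standard_normal(100)
        bold = _bold_on(atlas, lambda i, j, k: shared + 1e-3 * rng.standard_normal(100))
        strength, n_excl = intra_node_strength(bold, atlas, "roi1")
        assert strength >= np.arctanh(0.99)
        assert n_excl == 0

    def test_independent_noise_near_zero(self):
        atlas = make_block_atlas(1, roi_shape=(3, 3, 2), layout=(1, 1, 1))
        rng = np.random.default_rng(5)
        t = 2000
        bold = _bold_on(atlas, lambda i, j, k: rng.standard_normal(t))
        strength, _ = intra_node_strength(bold, atlas, "roi1")
        # per-pair null SD is 1/sqrt(T-3); the mean of 153 correlated pairs
        # stays well within a few such units
        assert abs(strength) < 4 / np.sqrt(t - 3)

    def test_too_few_usable_voxels_rejected(self):
        atlas = make_block_atlas(1, roi_shape=(2, 1, 1), layout=(1, 1, 1), gap=1)
        bold = _bold_on(atlas, lambda i, j, k: np.zeros(10))
        with pytest.raises(ValueError):
            intra_node_strength(bold, atlas, "roi1")


class TestGroupAverage:
    def _random_conn(self, seed, names=("a", "b", "c")):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((3, 3))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        return ConnMatrix(list(names), z)

    def test_single_matrix_identity(self):
        m = self._random_conn(0)
        avg = group_average_matrix([m])
        assert np.allclose(avg.z, m.z, equal_nan=True)

    def test_opposite_matrices_cancel(self):
        m = self._random_conn(1)
        neg = ConnMatrix(m.roi_order, -m.z)
        avg = group_average_matrix([m, neg])
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(avg.z[off], 0.0, atol=1e-12)

    def test_seven_matrix_mean_oracle(self):
        ms = [self._random_conn(s) for s in range(7)]
        avg = group_average_matrix(ms)
        stack = np.array([m.z for m in ms])
        assert np.allclose(avg.z, stack.mean(axis=0), equal_nan=True, atol=1e-12)
        assert avg.metadata["n"] == 7

    def test_roi_order_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_average_matrix([self._random_conn(0), self._random_conn(1, names=("x", "y", "z"))])


def test_merge_hemispheres_combines_paired_labels():
    atlas = make_block_atlas(4, roi_shape=(2, 2, 1),
                             roi_names=["M1", "M1", "S1", "S1"],
                             hemispheres=["L", "R", "L", "R"])
    merged = merge_hemispheres(atlas)
    assert merged.roi_names == ["M1", "S1"]
    assert (merged.roi_table["n_voxels"] == 8).all()
    assert set(np.unique(merged.labels)) == {0, 1, 2}
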