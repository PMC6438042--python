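"""Preprocessing chain contracts: OLS nuisance removal, strictly in-plane
smoothing, zero-phase bandpass, per-voxel z-scoring."""

import numpy as np
import pytest

from taumri.io import Bold4D, NuisanceSet, VolumeGeometry
from taumri.preproc import (PreprocConfig, bandpass_filter, build_design_matrix,
                            normalize_timeseries, preprocess_bold, regress_nuisance,
                            smooth_inplane)
from taumri.synthetic import default_base_corr, make_block_atlas, simulate_bold_dataset

TR = 2.84


def _bold_from_series(series, dims=(2, 2, 1)):
    series = np.asarray(series, dtype=float)
    data = np.broadcast_to(series, (*dims, series.size)).copy()
    geom = VolumeGeometry.from_voxel_size(dims, (0.182, 0.182, 0.5))
    return Bold4D(geom, data, tr=TR)


def _zero_nuisance(n, drift_order=2):
    return NuisanceSet(np.zeros(n), np.zeros((n, 6)), drift_order)


class TestRegressNuisance:
    def test_linear_ramp_fully_removed(self):
        bold = _bold_from_series(np.linspace(0, 1, 40))
        out = regress_nuisance(bold, _zero_nuisance(40), drift_order=1,
                               include_respiration=False, include_motion=False)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_respiration(self):
        n = 105
        rng = np.random.default_rng(0)
        resp = np.sin(2 * np.pi * 0.12 * TR * np.arange(n))
        s = np.sin(2 * np.pi * 0.04 * TR * np.arange(n)) + 0.7 * resp
        bold = _bold_from_series(s + 0.1 * rng.standard_normal(n))
        nuis = NuisanceSet(resp, np.zeros((n, 6)), 2)
        out = regress_nuisance(bold, nuis, include_motion=False)
        voxel = out.data[0, 0, 0]
        corr = np.corrcoef(voxel, resp)[0, 1]
        assert abs(corr) <= 1e-6

    def test_intercept_only_removes_mean(self):
        series = np.array([3.0, 5.0, 4.0, 8.0, 1.0, 3.0, 6.0, 2.0, 9.0, 4.0])
        bold = _bold_from_series(series)
        out = regress_nuisance(bold, _zero_nuisance(10, 0), drift_order=0,
                               include_respiration=False, include_motion=False)
        assert np.allclose(out.data[0, 0, 0], series - series.mean())

    def test_relative_orthogonality_to_full_design(self):
        n = 105
        rng = np.random.default_rng(1)
        nuis = NuisanceSet(rng.standard_normal(n), rng.standard_normal((n, 6)), 2)
        geom = VolumeGeometry.from_voxel_size((3, 3, 2), (0.182, 0.182, 0.5))
        bold = Bold4D(geom, rng.standard_normal((3, 3, 2, n)), tr=TR)
        out = regress_nuisance(bold, nuis)
        x = build_design_matrix(nuis, n, 2)
        resid = out.data.reshape(-1, n)
        dots = np.abs(resid @ x)
        scale = np.linalg.norm(resid, axis=1, keepdims=True) * np.linalg.norm(x, axis=0)
        assert np.all(dots / scale <= 1e-8)

    def test_rank_deficient_design_rejected(self):
        n = 40
        nuis = NuisanceSet(np.ones(n), np.zeros((n, 6)), 0)  # respiration == intercept
        bold = _bold_from_series(np.random.default_rng(0).standard_normal(n))
        with pytest.raises(ValueError, match="rank"):
            regress_nuisance(bold, nuis, drift_order=0, include_motion=False)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        bold = _bold_from_series(np.arange(10.0), dims=(5, 5, 2))
        out = smooth_inplane(bold, 0.0)
        assert np.array_equal(out.data, bold.data)

    def test_impulse_spread_matches_sigma(self):
        # FWHM 0.3 mm on 0.182 mm pixels -> sigma = 0.3/2.3548/0.182 = 0.70 px
        geom = VolumeGeometry.from_voxel_size((21, 21, 1), (0.182, 0.182, 0.5))
        data = np.zeros((21, 21, 1, 2))
        data[10, 10, 0, 0] = 1.0
        out = smooth_inplane(Bold4D(geom, data, tr=TR), 0.3).data[:, :, 0, 0]
        sigma_px = 0.3 / (2 * np.sqrt(2 * np.log(2))) / 0.182
        x = np.arange(21) - 10.0
        second_moment = np.sum(out * x[:, None] ** 2) / out.sum()
        assert np.sqrt(second_moment) == pytest.approx(sigma_px, rel=0.02)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_constant_image_unchanged(self):
        geom = VolumeGeometry.from_voxel_size((9, 9, 2), (0.182, 0.182, 0.5))
        data = np.full((9, 9, 2, 3), 7.0)
        out = smooth_inplane(Bold4D(geom, data, tr=TR), 0.3)
        assert np.allclose(out.data, 7.0, atol=1e-10)

    def test_no_smoothing_across_slices(self):
        geom = VolumeGeometry.from_voxel_size((9, 9, 2), (0.182, 0.182, 0.5))
        data = np.zeros((9, 9, 2, 2))
        data[:, :, 0, 0] = 1.0
        out = smooth_inplane(Bold4D(geom, data, tr=TR), 0.3)
        assert np.allclose(out.data[:, :, 1, 0], 0.0)

    def test_negative_fwhm_rejected(self):
        bold = _bold_from_series(np.arange(10.0))
        with pytest.raises(ValueError):
            smooth_inplane(bold, -0.1)


class TestBandpass:
    def _amplitude_after(self, freq, n=1024):
        t = np.arange(n) * TR
        s = np.sin(2 * np.pi * freq * t)
        out = bandpass_filter(s, TR, (0.01, 0.08))
        core = slice(n // 4, 3 * n // 4)  # avoid transients
        return np.max(np.abs(out[core]))

    def test_passband_amplitude_retained(self):
        assert self._amplitude_after(0.04) >= 0.9

    def test_stopband_attenuated(self):
        # 0.15 Hz lies above the 0.08 Hz edge: >= 20 dB rejection expected
        assert self._amplitude_after(0.15) <= 0.1

    def test_dc_removed(self):
        out = bandpass_filter(np.full(512, 5.0), TR, (0.01, 0.08))
        assert np.max(np.abs(out)) < 1e-6

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(128), TR, (0.01, 0.2))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass_filter(np.zeros(20), TR, (0.01, 0.08))


class TestNormalize:
    def test_zscore_definition(self):
        bold = _bold_from_series(np.array([1.0, 2.0, 3.0]))
        out, flagged = normalize_timeseries(bold)
        v = out.data[0, 0, 0]
        assert v.mean() == pytest.approx(0.0, abs=1e-12)
        assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert not flagged.any()

    def test_constant_voxel_zeroed_and_flagged(self):
        bold = _bold_from_series(np.full(8, 3.0))
        out, flagged = normalize_timeseries(bold)
        assert np.allclose(out.data, 0.0)
        assert flagged.all()

    def test_correlations_invariant_under_normalization(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 50))
        geom = VolumeGeometry.from_voxel_size((2, 1, 1), (0.2, 0.2, 0.5))
        bold = Bold4D(geom, np.stack([a, b])[:, None, None, :], tr=TR)
        out, _ = normalize_timeseries(bold)
        r_before = np.corrcoef(a, b)[0, 1]
        r_after = np.corrcoef(out.data[0, 0, 0], out.data[1, 0, 0])[0, 1]
        assert r_after == pytest.approx(r_before, abs=1e-12)


class TestFullChain:
    def test_chain_recovers_network_and_suppresses_nuisance(self):
        atlas = make_block_atlas(6)
        corr = default_base_corr(6)
        bold, nuis, truth = simulate_bold_dataset(atlas, corr, n_frames=105, seed=9)
        clean, flagged = preprocess_bold(bold, nuis)
        assert not flagged.any()
        # injected respiration is suppressed: median |corr| with the trace
        voxels = clean.data.reshape(-1, 105)
        resp = nuis.respiration - nuis.respiration.mean()
        resp /= np.linalg.norm(resp)
        rows = voxels - voxels.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(rows, axis=1)
        corr_with_resp = (rows @ resp) / np.where(norms == 0, 1.0, norms)
        assert np.median(np.abs(corr_with_resp)) <= 0.05

    def test_normalization_idempotent_at_chain_end(self):
        atlas = make_block_atlas(4, roi_shape=(2, 2, 2))
        corr = default_base_corr(4)
        bold, nuis, _ = simulate_bold_dataset(atlas, corr, n_frames=60, seed=4)
        clean, _ = preprocess_bold(bold, nuis)
        again, _ = normalize_timeseries(clean)
        assert np.allclose(again.data, clean.data, atol=1e-10)

    def test_invalid_band_for_tr(self):
        cfg = PreprocConfig(band=(0.01, 0.5))
        with pytest.raises(ValueError):
            cfg.validate(TR)
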