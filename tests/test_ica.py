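"""Masked-ICA oracles: whitening identities, source recovery on constructed
mixtures, cross-check against an independent FastICA implementation, and
mixture-model thresholding behaviour."""

from __future__ import annotations

import numpy as np
import pytest

from hypica import ica
from hypica.containers import MaskedMatrix


def _matrix(values):
    values = np.asarray(values, dtype=float)
    t, v = values.shape
    vox = np.argwhere(np.ones((v, 1, 1), dtype=bool))
    return MaskedMatrix(values=values, voxel_index=vox,
                        block_bounds=[((0, 0), (0, t))],
                        grid_shape=(v, 1, 1))


def _disjoint_sources(n_sources=3, v=300, rng=None):
    """Unit-variance maps with disjoint support (strongly non-Gaussian)."""
    rng = rng or np.random.default_rng(0)
    maps = np.zeros((n_sources, v))
    width = v // n_sources
    for k in range(n_sources):
        sl = slice(k * width, k * width + width // 3)
        maps[k, sl] = rng.gamma(2.0, 1.0, width // 3) + 1.0
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= maps.std(axis=1, keepdims=True)
    return maps


def _match_correlations(true_maps, est_maps):
    k, d = true_maps.shape[0], est_maps.shape[0]
    corr = np.abs(np.corrcoef(true_maps, est_maps)[:k, k:])
    out = []
    for _ in range(min(k, d)):
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        out.append(corr[i, j])
        corr[i, :] = -1
        corr[:, j] = -1
    return np.asarray(out)


class TestReduceAndWhiten:
    def test_full_rank_no_reduction_keeps_all_variance(self, rng):
        x = rng.standard_normal((50, 40))
        wh = ica.reduce_and_whiten(_matrix(x), 40)
        assert wh.retained_variance == pytest.approx(1.0, abs=1e-10)
        v = x.shape[1]
        np.testing.assert_allclose(wh.z @ wh.z.T / v, np.eye(40), atol=1e-8)

    def test_rank3_matrix_fully_captured_at_d3(self, rng):
        a = rng.standard_normal((30, 3))
        s = rng.standard_normal((3, 60))
        wh = ica.reduce_and_whiten(_matrix(a @ s), 3)
        assert wh.retained_variance == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(wh.back @ wh.z, a @ s, atol=1e-8)

    def test_d_beyond_rank_raises(self, rng):
        a = rng.standard_normal((30, 3))
        s = rng.standard_normal((3, 60))
        with pytest.raises(ValueError, match="rank"):
            ica.reduce_and_whiten(_matrix(a @ s), 5)

    def test_d_zero_raises(self, rng):
        with pytest.raises(ValueError):
            ica.reduce_and_whiten(_matrix(rng.standard_normal((10, 10))), 0)


class TestEstimateComponents:
    def test_recovers_disjoint_sources(self, rng):
        maps = _disjoint_sources(3, rng=rng)
        mixing = rng.standard_normal((120, 3))
        x = mixing @ maps
        wh = ica.reduce_and_whiten(_matrix(x), 3)
        comps = ica.estimate_components(wh, 3, seed=0)
        matched = _match_correlations(maps, comps.maps_z)
        assert np.all(matched >= 0.95)

    def test_single_source_d1(self, rng):
        maps = _disjoint_sources(1, rng=rng)
        x = rng.standard_normal((80, 1)) @ maps
        wh = ica.reduce_and_whiten(_matrix(x), 1)
        comps = ica.estimate_components(wh, 1, seed=0)
        assert abs(np.corrcoef(maps[0], comps.maps_z[0])[0, 1]) >= 0.95

    def test_deterministic_given_seed(self, rng):
        maps = _disjoint_sources(3, rng=rng)
        x = rng.standard_normal((100, 3)) @ maps
        wh = ica.reduce_and_whiten(_matrix(x), 3)
        a = ica.estimate_components(wh, 3, seed=7)
        b = ica.estimate_components(wh, 3, seed=7)
        np.testing.assert_array_equal(a.maps_z, b.maps_z)
        np.testing.assert_array_equal(a.mixing, b.mixing)

    def test_positive_skew_orientation(self, rng):
        from scipy.stats import skew

        maps = _disjoint_sources(3, rng=rng)
        x = rng.standard_normal((100, 3)) @ maps
        wh = ica.reduce_and_whiten(_matrix(x), 3)
        comps = ica.estimate_components(wh, 3, seed=0)
        assert np.all(skew(comps.maps_z, axis=1) >= 0)

    def test_reconstruction_within_discarded_variance(self, rng):
        x = rng.standard_normal((60, 200))
        x[:, :40] += np.outer(rng.standard_normal(60), np.ones(40)) * 3
        d = 4
        wh = ica.reduce_and_whiten(_matrix(x), d)
        comps = ica.estimate_components(wh, d, seed=0, threshold=False)
        recon = comps.mixing @ comps.maps_raw
        reduced = wh.back @ wh.z
        np.testing.assert_allclose(recon, reduced, atol=1e-8)

    def test_matches_reference_fastica_subspace(self, rng):
        """Independent cross-check: scikit-learn's FastICA on the same
        mixture recovers the same sources (up to order and sign)."""
        from sklearn.decomposition import FastICA

        maps = _disjoint_sources(3, v=400, rng=rng)
        x = rng.standard_normal((150, 3)) @ maps
        wh = ica.reduce_and_whiten(_matrix(x), 3)
        ours = ica.estimate_components(wh, 3, seed=0)
        ref = FastICA(n_components=3, random_state=0, max_iter=1000)
        ref_maps = ref.fit_transform(x.T).T  # spatial ICA: voxels as samples
        matched = _match_correlations(ref_maps, ours.maps_z)
        assert np.all(matched >= 0.95)


class TestMixtureThreshold:
    def test_recovers_injected_signal_tail(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        idx = rng.choice(n, size=int(0.05 * n), replace=False)
        x[idx] = 8.0 + rng.standard_normal(len(idx)) * 0.5
        fit = ica.mixture_threshold(x)
        hit = fit.retained[idx].mean()
        bg = np.ones(n, dtype=bool)
        bg[idx] = False
        false = fit.retained[bg].mean()
        assert hit >= 0.90
        assert false <= 0.01

    def test_pure_noise_retains_little_or_falls_back(self, rng):
        x = rng.standard_normal(1000)
        fit = ica.mixture_threshold(x)
        assert fit.retained.mean() <= 0.01 or fit.fallback

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ica.mixture_threshold(np.full(100, 3.0))


class TestScanDimensionalities:
    def test_matched_recovery_peaks_at_true_d(self, rng):
        true_d = 5
        maps = _disjoint_sources(true_d, v=500, rng=rng)
        x = rng.standard_normal((200, true_d)) @ maps
        x += 0.05 * rng.standard_normal(x.shape)
        mat = _matrix(x)
        scan = ica.scan_dimensionalities(mat, list(range(2, 9)), seed=0)
        mean_matched = {}
        for d, entry in scan.items():
            matched = _match_correlations(maps, entry["components"].maps_z)
            mean_matched[d] = matched.mean()
        best = max(mean_matched, key=mean_matched.get)
        assert best == true_d

    def test_single_entry_bookkeeping(self, rng):
        x = rng.standard_normal((40, 120))
        scan = ica.scan_dimensionalities(_matrix(x), [3], seed=0)
        assert list(scan) == [3]
        assert scan[3]["components"].n_components == 3
        assert scan[3]["label_volume"].shape == (120, 1, 1)

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            ica.scan_dimensionalities(_matrix(rng.standard_normal((10, 20))),
                                      [], seed=0)
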