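"""GFP, peaks, spatial correlation and the polarity-invariant k-means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microstates import (
    EEGRecording,
    KmeansConfig,
    compute_gfp,
    find_gfp_peaks,
    group_cluster,
    make_templates,
    map_correspondence,
    modified_kmeans,
    spatial_correlation,
)
from microstates import reference
from microstates.clustering import GfpSeries


class TestGfp:
    def test_constant_map_zero(self):
        rec = EEGRecording(np.full((8, 10), 7.0), 250.0)
        assert np.allclose(compute_gfp(rec).values, 0.0)

    def test_two_channel_analytic(self):
        rec = EEGRecording(np.array([[1.0], [-1.0]]), 250.0)
        assert compute_gfp(rec).values[0] == pytest.approx(1.0, abs=1e-14)

    def test_matches_naive_oracle(self, rng):
        data = rng.standard_normal((64, 1000))
        rec = EEGRecording(data, 250.0)
        assert np.allclose(compute_gfp(rec).values, reference.gfp_naive(data),
                           atol=1e-12)


class TestGfpPeaks:
    def _series(self, values, epochs=None):
        values = np.asarray(values, dtype=float)
        if epochs is None:
            epochs = np.array([[0, len(values)]])
        return GfpSeries(values, epochs, 250.0)

    def test_monotonic_no_peaks(self):
        assert len(find_gfp_peaks(self._series(np.arange(10)))) == 0

    def test_single_peak(self):
        assert find_gfp_peaks(self._series([0, 1, 0])).tolist() == [1]

    def test_no_peaks_across_epoch_boundary(self):
        v = [0, 1, 2, 3, 2, 1, 0, 1]
        peaks = find_gfp_peaks(self._series(v, np.array([[0, 4], [4, 8]])))
        assert peaks.tolist() == []  # index 3 is the last sample of epoch 1

    def test_matches_exhaustive_neighbor_scan(self, rng):
        t = np.arange(250) / 250.0
        v = np.abs(np.sin(2 * np.pi * 10 * t) * (1 + 0.5 * np.sin(2 * np.pi * t)))
        v += 0.01 * rng.standard_normal(250)
        peaks = find_gfp_peaks(self._series(v))
        brute = [i for i in range(1, 249) if v[i] > v[i - 1] and v[i] > v[i + 1]]
        assert peaks.tolist() == brute

    def test_plateau_head_counts(self):
        peaks = find_gfp_peaks(self._series([0, 2, 2, 2, 1, 0]))
        assert peaks.tolist() == [1]

    def test_min_distance_keeps_larger(self):
        peaks = find_gfp_peaks(self._series([0, 3, 0, 5, 0]), min_peak_distance=3)
        assert peaks.tolist() == [3]


class TestSpatialCorrelation:
    def test_self_and_negation(self, rng):
        a = rng.standard_normal(16)
        assert spatial_correlation(a, a) == pytest.approx(1.0, abs=1e-12)
        assert spatial_correlation(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_pearson(self):
        a = np.array([1.0, 2.0, -1.0, 0.5])
        b = np.array([0.3, 1.9, -2.0, 0.0])
        assert spatial_correlation(a, b) == pytest.approx(
            reference.pearson_naive(a, b), abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(ZeroDivisionError):
            spatial_correlation(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestModifiedKmeans:
    def _orthogonal_templates(self, n_ch=12, K=3):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((K, n_ch))
        m -= m.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(m.T)
        t = q[:, :K].T
        return t - t.mean(axis=1, keepdims=True)

    def test_noiseless_recovery_and_unit_gev(self, rng):
        t = self._orthogonal_templates()
        maps = t[rng.integers(0, 3, 150)] * rng.uniform(0.5, 2.0, (150, 1))
        ts, labels, gev = modified_kmeans(maps, 3, KmeansConfig(n_restarts=5, seed=1))
        assert gev == pytest.approx(1.0, abs=1e-10)
        pairs, table = map_correspondence(ts, ts)
        for planted in t:
            best = max(abs(spatial_correlation(planted, m)) for m in ts.maps)
            assert best == pytest.approx(1.0, abs=1e-9)

    def test_polarity_invariance_exact(self, rng):
        t = self._orthogonal_templates()
        maps = t[rng.integers(0, 3, 100)] + 0.1 * rng.standard_normal((100, 12))
        flips = rng.choice([-1.0, 1.0], size=(100, 1))
        cfg = KmeansConfig(n_restarts=4, seed=2)
        ts1, lab1, gev1 = modified_kmeans(maps, 3, cfg)
        ts2, lab2, gev2 = modified_kmeans(maps * flips, 3, cfg)
        assert np.array_equal(lab1, lab2)
        assert gev1 == gev2
        assert np.allclose(np.abs(ts1.maps), np.abs(ts2.maps), atol=1e-12)

    def test_gev_trace_nondecreasing(self, rng):
        maps = rng.standard_normal((80, 10))
        ts, _, _ = modified_kmeans(maps, 4, KmeansConfig(n_restarts=3, seed=3))
        assert np.all(np.diff(ts.gev_trace) >= -1e-12)

    def test_k_equals_n_gives_unit_gev(self, rng):
        maps = rng.standard_normal((8, 10))
        _, _, gev = modified_kmeans(maps, 8, KmeansConfig(n_restarts=30, seed=4))
        assert gev == pytest.approx(1.0, abs=1e-9)

    def test_channel_permutation_equivariance(self, rng):
        maps = rng.standard_normal((60, 10))
        perm = rng.permutation(10)
        cfg = KmeansConfig(n_restarts=4, seed=5)
        ts1, lab1, gev1 = modified_kmeans(maps, 3, cfg)
        ts2, lab2, gev2 = modified_kmeans(maps[:, perm], 3, cfg)
        assert np.array_equal(lab1, lab2)
        assert gev1 == pytest.approx(gev2, abs=1e-10)
        assert np.allclose(np.abs(ts1.maps[:, perm]), np.abs(ts2.maps), atol=1e-8)

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            modified_kmeans(rng.standard_normal((3, 8)), 5)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_recovery_under_noise_property(self, seed):
        """Recovered templates stay close to planted ones at moderate noise."""
        rng = np.random.default_rng(seed)
        t = make_templates(24, 4, seed=seed).maps
        idx = rng.integers(0, 4, 300)
        noise = 0.35 * rng.standard_normal((300, 24))
        maps = (t[idx] + noise) * rng.choice([-1.0, 1.0], (300, 1))
        ts, _, _ = modified_kmeans(maps, 4, KmeansConfig(n_restarts=8, seed=seed))
        _, table = map_correspondence(ts, ts)
        from microstates import TemplateSet

        pairs, table = map_correspondence(TemplateSet(t), ts)
        matched = np.mean([table[a - 1, b - 1] for a, b in pairs])
        assert matched > 0.9


class TestGroupCluster:
    def test_identical_subjects_recovered(self):
        ts = make_templates(16, 5, seed=6)
        group, _, _ = group_cluster([ts, ts, ts], 5, KmeansConfig(n_restarts=10, seed=7))
        pairs, table = map_correspondence(ts, group)
        assert np.mean([table[a - 1, b - 1] for a, b in pairs]) == pytest.approx(
            1.0, abs=1e-9)

    def test_sign_flipped_subjects_same_result(self):
        from microstates import TemplateSet

        ts = make_templates(16, 5, seed=8)
        flipped = TemplateSet(-ts.maps)
        cfg = KmeansConfig(n_restarts=10, seed=9)
        g1, _, _ = group_cluster([ts, ts], 5, cfg)
        g2, _, _ = group_cluster([ts, flipped], 5, cfg)
        assert np.allclose(np.abs(g1.maps), np.abs(g2.maps), atol=1e-9)

    def test_single_subject_rejected(self):
        ts = make_templates(16, 5, seed=10)
        with pytest.raises(ValueError, match="2 subjects"):
            group_cluster([ts], 5)
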