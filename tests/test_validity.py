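"""Validity criteria, per-criterion optima and the meta-criterion."""

import numpy as np
import pytest

from microstates import (
    KmeansConfig,
    make_templates,
    modified_kmeans,
    pairwise_dissimilarity,
)
from microstates import reference
from microstates.validity import (
    ValidityProfile,
    compute_validity_criteria,
    meta_criterion,
    select_optimal_k,
)


class TestDissimilarity:
    def test_identical_and_flipped_maps_distance_zero(self, rng):
        a = rng.standard_normal(8)
        d = pairwise_dissimilarity(np.vstack([a, a, -a]))
        assert np.allclose(d, 0.0, atol=1e-7)

    def test_orthogonal_maps_sqrt2(self):
        maps = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        d = pairwise_dissimilarity(maps)
        assert d[0, 1] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_zero_variance_map_signalled(self):
        with pytest.raises(ZeroDivisionError):
            pairwise_dissimilarity(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


def _cluster_instance(rng, n_ch=8, K=3, n=30, noise=0.4):
    t = make_templates(n_ch, K, seed=int(rng.integers(2**31 - 1))).maps
    idx = np.arange(n) % K
    maps = t[idx] + noise * rng.standard_normal((n, n_ch))
    maps *= rng.choice([-1.0, 1.0], (n, 1))
    return maps


class TestCriteria:
    def test_ideal_separation_limits(self, rng):
        """Two tight well-separated clusters at the true K: near-ideal values."""
        maps = _cluster_instance(rng, n_ch=16, K=2, n=40, noise=0.005)
        ts, labels, _ = modified_kmeans(maps, 2, KmeansConfig(n_restarts=5, seed=0))
        profile = compute_validity_criteria(maps, {2: (ts, labels)})
        assert profile.values["gamma"][2] == pytest.approx(1.0, abs=1e-9)
        assert profile.values["silhouette"][2] > 0.9
        assert profile.values["davies_bouldin"][2] < 0.1

    def test_degenerate_identical_maps(self, rng):
        a = rng.standard_normal(8)
        maps = np.tile(a, (10, 1)) * rng.choice([-1.0, 1.0], (10, 1))
        ts, labels, _ = modified_kmeans(maps, 2, KmeansConfig(n_restarts=2, seed=1))
        profile = compute_validity_criteria(maps, {2: (ts, labels)})
        assert profile.values["silhouette"][2] == 0.0
        assert any("degenerate" in line for line in profile.log)

    def test_all_criteria_match_naive_oracles(self, rng):
        """Random 8-channel instances vs. brute-force references, K in 2..4."""
        maps = _cluster_instance(rng, n_ch=8, K=3, n=30, noise=0.4)
        d = pairwise_dissimilarity(maps)
        assert np.allclose(d, reference.dissimilarity_naive(maps), atol=1e-10)
        segms, w = {}, {}
        for K in (2, 3, 4):
            ts, labels, _ = modified_kmeans(maps, K, KmeansConfig(n_restarts=8, seed=K))
            segms[K] = (ts, labels)
            dt = np.array(
                [[np.sqrt(2 * (1 - min(abs(reference.pearson_naive(x, t)), 1.0)))
                  for t in ts.maps] for x in maps])
            w[K] = reference.dispersion_naive(dt, labels)
        profile = compute_validity_criteria(maps, segms)
        for K in (2, 3, 4):
            ts, labels = segms[K]
            dt = np.array(
                [[np.sqrt(2 * (1 - min(abs(reference.pearson_naive(x, t)), 1.0)))
                  for t in ts.maps] for x in maps])
            d_t = reference.dissimilarity_naive(ts.maps)
            assert profile.values["gamma"][K] == pytest.approx(
                reference.gamma_naive(d, labels), abs=1e-8)
            assert profile.values["silhouette"][K] == pytest.approx(
                reference.silhouette_naive(d, labels), abs=1e-8)
            assert profile.values["davies_bouldin"][K] == pytest.approx(
                reference.davies_bouldin_naive(dt, d_t, labels), abs=1e-8)
            assert profile.values["point_biserial"][K] == pytest.approx(
                reference.point_biserial_naive(d, labels), abs=1e-8)
            assert profile.values["dunn"][K] == pytest.approx(
                reference.dunn_naive(d, labels), abs=1e-8)
            assert profile.values["cross_validation"][K] == pytest.approx(
                reference.cross_validation_naive(maps, ts.maps, labels), abs=1e-8)
        assert profile.values["krzanowski_lai"][3] == pytest.approx(
            reference.krzanowski_lai_naive(w, 3, maps.shape[1]), abs=1e-8)

    def test_sign_flip_and_relabel_invariance(self, rng):
        maps = _cluster_instance(rng)
        ts, labels, _ = modified_kmeans(maps, 3, KmeansConfig(n_restarts=5, seed=2))
        p1 = compute_validity_criteria(maps, {3: (ts, labels)})
        # flip map signs and relabel clusters
        flips = rng.choice([-1.0, 1.0], (len(maps), 1))
        perm = np.array([2, 0, 1])
        from microstates import TemplateSet

        ts2 = TemplateSet(ts.maps[perm] * rng.choice([-1.0, 1.0], (3, 1)))
        relabeled = np.argsort(perm)[labels]
        p2 = compute_validity_criteria(maps * flips, {3: (ts2, relabeled)})
        for c in p1.values:
            v1, v2 = p1.values[c][3], p2.values[c][3]
            if np.isnan(v1) and np.isnan(v2):
                continue
            assert v1 == pytest.approx(v2, abs=1e-9)


class TestSelection:
    def _profile(self, per_criterion):
        ks = sorted({k for d in per_criterion.values() for k in d})
        return ValidityProfile(ks, per_criterion)

    def test_unanimous_optimum(self):
        vals = {c: {4: 0.1, 5: 0.9, 6: 0.2} for c in
                ("gamma", "silhouette", "point_biserial", "dunn", "krzanowski_lai")}
        vals["davies_bouldin"] = {4: 0.9, 5: 0.1, 6: 0.5}
        vals["cross_validation"] = {4: 0.9, 5: 0.1, 6: 0.5}
        profile = self._profile(vals)
        optima = select_optimal_k(profile)
        assert set(optima.values()) == {5}
        assert meta_criterion(optima) == 5

    def test_flat_criterion_takes_smallest_k(self):
        vals = {"gamma": {2: 0.5, 3: 0.5, 4: 0.5}}
        profile = self._profile(vals)
        assert select_optimal_k(profile)["gamma"] == 2

    def test_all_nan_criterion_excluded(self):
        vals = {"gamma": {2: 0.1, 3: 0.9}, "dunn": {2: np.nan, 3: np.nan}}
        profile = self._profile(vals)
        optima = select_optimal_k(profile)
        assert "dunn" not in optima
        assert any("excluded" in line for line in profile.log)


class TestMetaCriterion:
    @pytest.mark.parametrize(
        "optima, expected",
        [
            ([5, 5, 5, 5, 5, 5, 5], 5),
            ([4, 4, 5, 5, 5, 6, 7], 5),
            ([4, 5, 6, 7], 5),   # even count -> lower middle value
            ([3, 9], 3),
        ],
    )
    def test_median_rule(self, optima, expected):
        assert meta_criterion(optima) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            meta_criterion([])
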