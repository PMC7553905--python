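"""Distributed inverse, standardization, thresholding, voxel statistics."""

import numpy as np
import pytest

from microstates import (
    InverseConfig,
    apply_inverse,
    build_inverse_operator,
    compute_sources,
    microstate_source_map,
    percentile_threshold,
    standardize_sources,
    toy_leadfield,
    voxelwise_randomization,
)


@pytest.fixture(scope="module")
def lf():
    return toy_leadfield(64, 200, seed=42)


def _planted_data(lf, point, rng, n_t=100):
    moment = rng.standard_normal(3)
    moment /= np.linalg.norm(moment)
    topo = lf.gain[:, 3 * point: 3 * point + 3] @ moment
    waveform = np.sin(2 * np.pi * 10 * np.arange(n_t) / 250.0)
    return np.outer(topo, waveform), topo


class TestInverseOperator:
    @pytest.mark.parametrize("point_rank", [0, 1, 2])
    def test_planted_source_peak_in_neighborhood(self, lf, rng, point_rank):
        """Resolution-normalized inverse localizes a noiseless source."""
        ecc = np.linalg.norm(lf.positions, axis=1)
        point = int(np.flatnonzero((ecc > 0.5) & (ecc < 0.8))[point_rank])
        data, _ = _planted_data(lf, point, rng)
        cfg = InverseConfig(snr=100.0, weighting="none", normalization="resolution")
        est = compute_sources(data, lf, cfg)
        peak = int(np.argmax(est.magnitudes.mean(axis=1)))
        dists = np.linalg.norm(lf.positions - lf.positions[point], axis=1)
        assert peak in set(np.argsort(dists)[:4].tolist())

    def test_large_lambda_shrinks_to_zero(self, lf, rng):
        data, _ = _planted_data(lf, 5, rng)
        op_small = build_inverse_operator(lf, InverseConfig(lam=1e-6))
        op_huge = build_inverse_operator(lf, InverseConfig(lam=1e12))
        small = apply_inverse(data, op_small, lf.positions).magnitudes
        huge = apply_inverse(data, op_huge, lf.positions).magnitudes
        assert huge.max() < 1e-6 * small.max()

    def test_common_offset_invariance(self, lf, rng):
        data, _ = _planted_data(lf, 10, rng)
        op = build_inverse_operator(lf, InverseConfig())
        a = apply_inverse(data, op, lf.positions).magnitudes
        b = apply_inverse(data + 13.0, op, lf.positions).magnitudes
        assert np.allclose(a, b, atol=1e-9 * a.max())

    def test_forward_inverse_small_residual(self, rng):
        """Unweighted inverse at tiny lambda nearly reproduces the data."""
        lf_small = toy_leadfield(32, 100, seed=7)
        data, _ = _planted_data(lf_small, 3, rng, n_t=10)
        op = build_inverse_operator(lf_small, InverseConfig(lam=1e-12, weighting="none"))
        moments = op @ data
        recon = lf_small.gain @ moments
        resid = np.linalg.norm(recon - data) / np.linalg.norm(data)
        assert resid < 1e-3


class TestStandardize:
    def test_unit_temporal_sd(self, lf, rng):
        data, _ = _planted_data(lf, 4, rng)
        data += 0.01 * rng.standard_normal(data.shape)
        op = build_inverse_operator(lf, InverseConfig())
        est = standardize_sources(apply_inverse(data, op, lf.positions))
        sd = est.magnitudes.std(axis=1)
        ok = ~est.degenerate
        assert np.allclose(sd[ok], 1.0, atol=1e-10)

    def test_scale_invariance(self, lf, rng):
        data, _ = _planted_data(lf, 4, rng)
        op = build_inverse_operator(lf, InverseConfig())
        a = standardize_sources(apply_inverse(data, op, lf.positions)).magnitudes
        b = standardize_sources(apply_inverse(10 * data, op, lf.positions)).magnitudes
        assert np.allclose(a, b, atol=1e-10)

    def test_constant_point_flagged(self):
        from microstates import SourceEstimate

        est = SourceEstimate(np.vstack([np.ones(10), np.arange(10.0)]),
                             np.zeros((2, 3)))
        out = standardize_sources(est)
        assert out.degenerate[0] and not out.degenerate[1]
        assert np.all(out.magnitudes[0] == 0.0)


class TestMicrostateSourceMap:
    def test_single_label_equals_temporal_mean(self, lf, rng):
        data, _ = _planted_data(lf, 4, rng)
        op = build_inverse_operator(lf, InverseConfig())
        est = apply_inverse(data, op, lf.positions)
        labels = np.ones(data.shape[1], dtype=int)
        m = microstate_source_map(est, labels, 1)
        assert np.allclose(m, est.magnitudes.mean(axis=1))
        assert np.all(np.isnan(microstate_source_map(est, labels, 2)))

    def test_joint_time_permutation_invariance(self, lf, rng):
        data, _ = _planted_data(lf, 4, rng)
        op = build_inverse_operator(lf, InverseConfig())
        est = apply_inverse(data, op, lf.positions)
        labels = rng.integers(1, 3, data.shape[1])
        perm = rng.permutation(data.shape[1])
        from microstates import SourceEstimate

        est_p = SourceEstimate(est.magnitudes[:, perm], est.positions)
        m1 = microstate_source_map(est, labels, 1)
        m2 = microstate_source_map(est_p, labels[perm], 1)
        assert np.allclose(m1, m2)


class TestPercentileThreshold:
    def test_100_distinct_values_q95_keeps_5(self, rng):
        mask = percentile_threshold(rng.permutation(100).astype(float), 95.0)
        assert mask.sum() == 5

    def test_all_equal_empty_mask(self):
        assert percentile_threshold(np.full(50, 3.3), 95.0).sum() == 0

    def test_matches_sort_oracle(self, rng):
        v = rng.standard_normal(137)
        mask = percentile_threshold(v, 95.0)
        thr = np.percentile(v, 95.0)
        oracle = {i for i, x in enumerate(v) if x > thr}
        assert set(np.flatnonzero(mask).tolist()) == oracle


class TestVoxelwiseRandomization:
    def test_identical_maps_nothing_significant(self, rng):
        maps = rng.standard_normal((12, 50))
        mask = np.ones(50, dtype=bool)
        sig, p = voxelwise_randomization(maps, maps.copy(), mask, alpha=0.005)
        assert sig.sum() == 0
        assert np.all(p[mask] == 1.0)

    def test_planted_difference_detected_exclusively(self, rng):
        base = rng.standard_normal((12, 50))
        maps_b = base.copy()
        maps_b[:, 17] += 1.0 + 0.1 * rng.random(12)
        mask = np.zeros(50, dtype=bool)
        mask[[3, 17, 30]] = True
        # other retained points have identical paired values -> degenerate p=1
        sig, p = voxelwise_randomization(maps_b, base, mask, alpha=0.005)
        assert sig[17]
        assert sig.sum() == 1
        assert p[17] == pytest.approx(2.0 / 4096.0)

    def test_alpha_one_flags_all_retained(self, rng):
        a = rng.standard_normal((5, 20))
        b = a + rng.standard_normal((5, 20))
        mask = np.ones(20, dtype=bool)
        sig, _ = voxelwise_randomization(a, b, mask, alpha=1.0000001)
        assert sig.sum() == 20

    def test_masked_out_points_untested(self, rng):
        a = rng.standard_normal((6, 10))
        b = rng.standard_normal((6, 10))
        mask = np.zeros(10, dtype=bool)
        mask[2] = True
        sig, p = voxelwise_randomization(a, b, mask)
        assert np.isnan(p[~mask]).all()
        assert not sig[~mask].any()
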