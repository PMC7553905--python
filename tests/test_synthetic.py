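"""Generator properties: planted templates, coverage, durations, carriers."""

import itertools

import numpy as np
import pytest
from scipy import signal as sp_signal

from microstates import (
    GeneratorConfig,
    GroupDesign,
    make_templates,
    simulate_group,
    simulate_recording,
    spatial_correlation,
    toy_leadfield,
)
from microstates.backfit import LabelSequence
from microstates.synthetic import jitter_templates


class TestMakeTemplates:
    def test_centered_unit_norm(self):
        ts = make_templates(64, 5, seed=1, max_similarity=0.5)
        assert ts.maps.shape == (5, 64)
        assert np.allclose(ts.maps.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(ts.maps, axis=1), 1.0)

    def test_deterministic(self):
        a = make_templates(64, 5, seed=1).maps
        b = make_templates(64, 5, seed=1).maps
        assert np.array_equal(a, b)

    def test_pairwise_separation_exhaustive(self):
        ts = make_templates(64, 5, seed=1, max_similarity=0.5)
        corrs = [abs(spatial_correlation(a, b))
                 for a, b in itertools.combinations(ts.maps, 2)]
        assert len(corrs) == 10
        assert max(corrs) <= 0.5

    def test_infeasible_separation_raises(self):
        with pytest.raises(RuntimeError):
            make_templates(4, 3, seed=0, max_similarity=0.01, max_attempts=50)


class TestSimulateRecording:
    def test_noiseless_samples_match_templates(self):
        cfg = GeneratorConfig(n_channels=16, n_maps=3, epoch_length=2.0,
                              snr=np.inf, seed=3)
        ts = make_templates(16, 3, seed=3)
        rec, gt = simulate_recording(cfg, ts)
        # at every nonzero time point |corr| with the generating template is 1
        for t in range(0, rec.n_times, 7):
            x = rec.data[:, t]
            if np.linalg.norm(x - x.mean()) < 1e-9:
                continue
            r = spatial_correlation(x, ts.maps[gt.labels[t] - 1])
            assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_mean_segment_duration(self):
        cfg = GeneratorConfig(n_channels=16, n_maps=4, epoch_length=60.0,
                              mean_duration_ms=80.0, seed=4)
        ts = make_templates(16, 4, seed=4)
        rec, gt = simulate_recording(cfg, ts)
        seq = LabelSequence(gt.labels, gt.epochs, cfg.sfreq, 4)
        lens = [e - s for _, s, e in seq.runs()]
        mean_ms = np.mean(lens) * 1000.0 / cfg.sfreq
        assert mean_ms == pytest.approx(80.0, rel=0.10)

    def test_degenerate_coverage_single_state(self):
        cfg = GeneratorConfig(n_channels=16, n_maps=3, epoch_length=2.0, seed=5)
        ts = make_templates(16, 3, seed=5)
        _, gt = simulate_recording(cfg, ts, coverage=np.array([1.0, 0.0, 0.0]))
        assert np.all(gt.labels == 1)

    def test_coverage_must_sum_to_one(self):
        cfg = GeneratorConfig(n_channels=16, n_maps=3, epoch_length=2.0, seed=5)
        ts = make_templates(16, 3, seed=5)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_recording(cfg, ts, coverage=np.array([0.5, 0.2, 0.2]))

    def test_bit_identical_for_same_seed(self):
        cfg = GeneratorConfig(n_channels=16, n_maps=3, epoch_length=2.0, seed=6)
        a, _ = simulate_recording(cfg)
        b, _ = simulate_recording(cfg)
        assert np.array_equal(a.data, b.data)

    def test_coverage_fractions_sum_to_one(self):
        cfg = GeneratorConfig(n_channels=16, n_maps=4, epoch_length=10.0, seed=7)
        _, gt = simulate_recording(cfg)
        assert gt.realized_coverage().sum() == pytest.approx(1.0, abs=1e-12)

    def test_spectral_fidelity_alpha_carrier(self):
        """Power of the concatenated map-m segments peaks in its carrier band."""
        cfg = GeneratorConfig(
            n_channels=8, n_maps=2, epoch_length=30.0, snr=np.inf,
            carrier_bands=[(8.5, 12.0), (20.0, 24.0)], mean_duration_ms=400.0,
            seed=8,
        )
        ts = make_templates(8, 2, seed=8)
        rec, gt = simulate_recording(cfg, ts)
        # project onto template 1 and take the Welch spectrum of its segments
        course = ts.maps[0] @ rec.data
        course[gt.labels != 1] = 0.0
        f, p = sp_signal.welch(course, fs=cfg.sfreq, nperseg=1024)
        peak = f[np.argmax(p)]
        assert 8.5 <= peak <= 12.0

    def test_polarity_flip_prob_changes_only_signs(self):
        base = dict(n_channels=8, n_maps=2, epoch_length=2.0, snr=np.inf, seed=9)
        ts = make_templates(8, 2, seed=9)
        rec0, gt0 = simulate_recording(
            GeneratorConfig(**base, polarity_flip_prob=0.0), ts)
        rec1, gt1 = simulate_recording(
            GeneratorConfig(**base, polarity_flip_prob=1.0), ts)
        assert np.array_equal(gt0.labels, gt1.labels)
        assert np.allclose(np.abs(rec0.data), np.abs(rec1.data), atol=1e-12)


class TestSimulateGroup:
    def test_zero_delta_identical_coverages(self):
        d = GroupDesign(delta=0.0)
        cov_a, cov_b = d.condition_coverages(5)
        assert np.array_equal(cov_a, cov_b)

    def test_planted_coverage_difference_exact(self):
        d = GroupDesign(delta=0.10)
        cov_a, cov_b = d.condition_coverages(5)
        diff = cov_a - cov_b
        assert diff[2] == pytest.approx(+0.10, abs=1e-12)
        assert diff[3] == pytest.approx(-0.10, abs=1e-12)
        assert np.allclose(diff[[0, 1, 4]], 0.0, atol=1e-12)

    def test_infeasible_delta_rejected(self):
        d = GroupDesign(delta=0.9)
        with pytest.raises(ValueError, match="infeasible"):
            d.condition_coverages(5)

    def test_jitter_hits_target_correlation(self, rng):
        group = make_templates(64, 5, seed=10)
        corrs = []
        for _ in range(20):
            sub = jitter_templates(group, 0.9, rng)
            corrs += [abs(spatial_correlation(a, b))
                      for a, b in zip(group.maps, sub.maps)]
        assert 0.85 <= np.mean(corrs) <= 0.95

    def test_group_output_structure(self):
        d = GroupDesign(n_subjects=2)
        cfg = GeneratorConfig(n_channels=16, epoch_length=2.0, seed=20)
        out = simulate_group(d, cfg)
        assert set(out) == {"DE", "NE"}
        assert len(out["DE"]) == 2
        rec, gt = out["DE"][0]
        assert rec.condition == "DE"
        assert gt.templates.maps.shape == (5, 16)


class TestToyLeadfield:
    def test_columns_average_referenced(self):
        lf = toy_leadfield(32, 50, seed=0)
        assert np.allclose(lf.gain.sum(axis=0), 0.0, atol=1e-10)

    def test_superficial_stronger_than_deep(self):
        """A superficial source projects more strongly than a deep one."""
        from microstates.synthetic import _sphere_potential, fibonacci_positions

        elec = fibonacci_positions(64)
        deep = _sphere_potential(elec, np.array([0.0, 0.0, 0.1]))
        shallow = _sphere_potential(elec, np.array([0.0, 0.0, 0.8]))
        assert np.linalg.norm(shallow) > np.linalg.norm(deep)

    def test_central_dipole_matches_closed_form(self):
        """Series limit at the centre equals 3 (m . e) / (4 pi sigma R^2)."""
        from microstates.synthetic import _sphere_potential, fibonacci_positions

        elec = fibonacci_positions(16)
        near = _sphere_potential(elec, np.array([0.0, 0.0, 1e-9]))
        central = _sphere_potential(elec, np.array([0.0, 0.0, 0.0]))
        assert np.allclose(near, central, atol=1e-8)

    def test_requires_interior_sources(self):
        with pytest.raises(ValueError):
            toy_leadfield(32, 10, seed=0, max_eccentricity=1.0)
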