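"""End-to-end validation experiments on synthetic ground truth.

Each function here sets up a planted-truth experiment at desk scale
(64 channels, 250 Hz, 30-s epochs, 20 subjects unless noted), runs the
relevant pipeline stages from scratch, and measures how well the planted
structure is recovered.  They are used both by the acceptance script and by
the acceptance test suite; all randomness derives from the single ``seed``
argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import reference
from .backfit import backfit_labels, compute_gev, map_correspondence, metrics_table
from .clustering import KmeansConfig, TemplateSet, compute_gfp, find_gfp_peaks, \
    group_cluster, modified_kmeans, _normalize_maps
from .core import EEGRecording
from .sources import InverseConfig, compute_sources, microstate_source_map, \
    percentile_threshold, standardize_sources, voxelwise_randomization
from .spectral import SpectralConfig, band_power_by_microstate, morlet_tf
from .stats import paired_randomization_test, rm_anova_2xk
from .synthetic import GeneratorConfig, GroupDesign, jitter_templates, \
    make_templates, simulate_group, simulate_recording, toy_leadfield
from .validity import choose_k, compute_validity_criteria, pairwise_dissimilarity

__all__ = [
    "template_recovery",
    "metacriterion_recovery",
    "oracle_deviation",
    "polarity_invariance",
    "anova_type1_error",
    "exhaustive_signflip_match",
    "signflip_uniformity",
    "dissociation_recovery",
    "spectral_sanity",
    "source_sanity",
]

_SEED_MOD = 2**31 - 1


def _sub_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % _SEED_MOD)


def _peak_maps(rec: EEGRecording) -> np.ndarray:
    gfp = compute_gfp(rec)
    peaks = find_gfp_peaks(gfp)
    return rec.data[:, peaks].T


# --------------------------------------------------------------------------
# 1. template recovery
# --------------------------------------------------------------------------

def template_recovery(
    seed: int = 0,
    n_subjects: int = 20,
    n_channels: int = 64,
    K: int = 5,
    snr: float = 2.0,          # amplitude ratio 2 = 6 dB
    subject_jitter: float = 0.9,
    n_restarts: int = 20,
) -> float:
    """Mean |corr| between planted and recovered group templates.

    Each subject contributes one 30-s recording built from a jittered copy
    of the planted group maps; subject-level k-means feeds a group-level
    clustering, and the recovered group maps are matched to the planted
    ones by optimal assignment.
    """
    group = make_templates(n_channels, K, seed=_sub_seed(seed, 1))
    rng = np.random.default_rng(_sub_seed(seed, 2))
    subject_sets = []
    for s in range(n_subjects):
        templates = jitter_templates(group, subject_jitter, rng)
        cfg = GeneratorConfig(
            n_channels=n_channels, n_maps=K, snr=snr,
            seed=_sub_seed(seed, 100 + s),
        )
        rec, _ = simulate_recording(cfg, templates)
        maps = _peak_maps(rec)
        ts, _, _ = modified_kmeans(
            maps, K, KmeansConfig(n_restarts=n_restarts, max_iter=100,
                                  seed=_sub_seed(seed, 200 + s))
        )
        subject_sets.append(ts)
    group_ts, _, _ = group_cluster(
        subject_sets, K,
        KmeansConfig(n_restarts=2 * n_restarts, max_iter=100, seed=_sub_seed(seed, 3)),
    )
    pairs, table = map_correspondence(group, group_ts)
    return float(np.mean([table[a - 1, b - 1] for a, b in pairs]))


# --------------------------------------------------------------------------
# 2. meta-criterion recovery
# --------------------------------------------------------------------------

def _well_separated_maps(
    n_channels: int, K: int, n_maps: int, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Peak-map sample: planted templates plus small tangential noise."""
    templates = make_templates(n_channels, K, seed=int(rng.integers(_SEED_MOD)))
    out = np.empty((n_maps, n_channels))
    for i in range(n_maps):
        k = i % K
        e = rng.standard_normal(n_channels)
        e -= e.mean()
        e /= np.linalg.norm(e)
        v = templates.maps[k] + noise * e
        sign = -1.0 if rng.random() < 0.5 else 1.0
        out[i] = sign * v / np.linalg.norm(v)
    return out


def metacriterion_recovery(
    seed: int = 0,
    n_runs: int = 20,
    K_true: int = 5,
    n_channels: int = 64,
    n_maps: int = 300,
    noise: float = 0.35,
    k_min: int = 2,
    k_max: int = 12,
    n_restarts: int = 10,
) -> float:
    """Fraction of seeded runs in which the meta-criterion returns K_true."""
    hits = 0
    for r in range(n_runs):
        rng = np.random.default_rng(_sub_seed(seed, 300 + r))
        maps = _well_separated_maps(n_channels, K_true, n_maps, noise, rng)
        meta_k, _, _ = choose_k(
            maps, k_min, k_max,
            KmeansConfig(n_restarts=n_restarts, max_iter=100,
                         seed=_sub_seed(seed, 400 + r)),
        )
        hits += meta_k == K_true
    return hits / n_runs


# --------------------------------------------------------------------------
# 3. oracle equivalence
# --------------------------------------------------------------------------

def oracle_deviation(seed: int = 0) -> float:
    """Max |difference| between package quantities and naive references.

    Covers GFP, spatial correlation, GEV, segment statistics and all seven
    validity criteria on random small instances.
    """
    rng = np.random.default_rng(seed)
    dev = 0.0

    # GFP and spatial correlation
    data = rng.standard_normal((16, 400))
    rec = EEGRecording(data, 250.0)
    dev = max(dev, float(np.max(np.abs(
        compute_gfp(rec).values - reference.gfp_naive(data)))))
    from .clustering import spatial_correlation

    a, b = rng.standard_normal((2, 16))
    dev = max(dev, abs(spatial_correlation(a, b) - reference.pearson_naive(a, b)))

    # GEV + segment statistics on a labelled recording
    templates = make_templates(16, 4, seed=_sub_seed(seed, 5))
    cfg = GeneratorConfig(n_channels=16, n_maps=4, sfreq=250.0, epoch_length=2.0,
                          n_epochs=2, snr=3.0, seed=_sub_seed(seed, 6))
    rec, gt = simulate_recording(cfg, templates)
    seq = backfit_labels(rec, templates)
    gev = compute_gev(rec, templates, seq)
    gev_ref = reference.gev_naive(rec.data, templates.maps, seq.labels)
    dev = max(dev, float(np.max(np.abs(gev - gev_ref))))
    from .backfit import segment_statistics

    stats = segment_statistics(seq)
    dur, occ, cov = reference.segment_stats_naive(
        seq.labels, seq.epochs, seq.sfreq, seq.n_maps)
    for col, ref_vals in (("mean_duration_ms", dur), ("occurrence_hz", occ),
                          ("coverage", cov)):
        got = stats[col].to_numpy()
        mask = ~np.isnan(ref_vals)
        dev = max(dev, float(np.max(np.abs(got[mask] - ref_vals[mask]), initial=0.0)))

    # the seven validity criteria on a small instance
    maps = _well_separated_maps(8, 3, 30, 0.4, rng)
    d = pairwise_dissimilarity(maps)
    dev = max(dev, float(np.max(np.abs(d - reference.dissimilarity_naive(maps)))))
    segms = {}
    for K in (2, 3, 4):
        ts, labels, _ = modified_kmeans(
            maps, K, KmeansConfig(n_restarts=10, seed=_sub_seed(seed, 7)))
        segms[K] = (ts, labels)
    profile = compute_validity_criteria(maps, segms)
    unit_maps, _ = _normalize_maps(maps)
    w: dict[int, float] = {}
    for K in (2, 3, 4):
        ts, labels = segms[K]
        t_unit, _ = _normalize_maps(ts.maps)
        dt = np.array([[np.sqrt(2 * (1 - min(abs(reference.pearson_naive(m, t)), 1.0)))
                        for t in ts.maps] for m in maps])
        d_templates = reference.dissimilarity_naive(ts.maps)
        w[K] = reference.dispersion_naive(dt, labels)
        checks = {
            "gamma": reference.gamma_naive(d, labels),
            "silhouette": reference.silhouette_naive(d, labels),
            "davies_bouldin": reference.davies_bouldin_naive(dt, d_templates, labels),
            "point_biserial": reference.point_biserial_naive(d, labels),
            "dunn": reference.dunn_naive(d, labels),
            "cross_validation": reference.cross_validation_naive(maps, ts.maps, labels),
        }
        for crit, ref_val in checks.items():
            dev = max(dev, abs(profile.values[crit][K] - ref_val))
    # KL at K=3 from the naive dispersions
    kl_ref = reference.krzanowski_lai_naive(w, 3, maps.shape[1])
    dev = max(dev, abs(profile.values["krzanowski_lai"][3] - kl_ref))
    return dev


# --------------------------------------------------------------------------
# 4. polarity invariance
# --------------------------------------------------------------------------

def polarity_invariance(seed: int = 0) -> float:
    """Max change in labels/assignments/metrics under random sign flips (exact 0)."""
    rng = np.random.default_rng(seed)
    templates = make_templates(32, 4, seed=_sub_seed(seed, 8))
    cfg = GeneratorConfig(n_channels=32, n_maps=4, epoch_length=4.0, snr=4.0,
                          seed=_sub_seed(seed, 9))
    rec, _ = simulate_recording(cfg, templates)
    maps = _peak_maps(rec)
    flip_m = rng.choice([-1.0, 1.0], size=(len(maps), 1))
    km_cfg = KmeansConfig(n_restarts=5, seed=_sub_seed(seed, 10))
    ts1, lab1, gev1 = modified_kmeans(maps, 4, km_cfg)
    ts2, lab2, gev2 = modified_kmeans(maps * flip_m, 4, km_cfg)
    dev = float(np.max(np.abs(lab1 - lab2), initial=0.0))
    dev = max(dev, abs(gev1 - gev2))
    dev = max(dev, float(np.max(np.abs(np.abs(ts1.maps) - np.abs(ts2.maps)))))

    flip_t = rng.choice([-1.0, 1.0], size=(templates.n_maps, 1))
    flip_s = rng.choice([-1.0, 1.0], size=(1, rec.n_times))
    rec_flipped = rec.copy_with(data=rec.data * flip_s)
    templates_flipped = TemplateSet(templates.maps * flip_t)
    seq1 = backfit_labels(rec, templates)
    seq2 = backfit_labels(rec_flipped, templates_flipped)
    dev = max(dev, float(np.max(np.abs(seq1.labels - seq2.labels), initial=0.0)))
    m1 = metrics_table(rec, templates, seq1)
    m2 = metrics_table(rec_flipped, templates_flipped, seq2)
    for col in ("mean_duration_ms", "occurrence_hz", "coverage", "gev"):
        x, y = m1[col].to_numpy(), m2[col].to_numpy()
        ok = ~(np.isnan(x) & np.isnan(y))
        dev = max(dev, float(np.max(np.abs(x[ok] - y[ok]), initial=0.0)))
    return dev


# --------------------------------------------------------------------------
# 5. statistics calibration
# --------------------------------------------------------------------------

def anova_type1_error(
    seed: int = 0, n_sims: int = 1000, n_subjects: int = 20, K: int = 5,
    alpha: float = 0.05,
) -> float:
    """Interaction rejection rate (GG-corrected) under an exchangeable null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        y = rng.standard_normal((n_subjects, 2, K))
        res = rm_anova_2xk(y)
        rejections += res["interaction"].p_gg < alpha
    return rejections / n_sims


def exhaustive_signflip_match(seed: int = 0, n_max: int = 12) -> float:
    """Max |p difference| between the package test and full enumeration.

    The reference enumerates all sign patterns with ``itertools.product``;
    agreement must be bit-exact (0.0).
    """
    import itertools

    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in range(3, n_max + 1):
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        res = paired_randomization_test(a, b)
        assert res.exhaustive
        d = a - b
        t_obs = abs(np.mean(d))
        count = 0
        total = 0
        for signs in itertools.product((-1.0, 1.0), repeat=n):
            total += 1
            if abs(np.mean(np.array(signs) * d)) >= t_obs - 1e-12 * max(1.0, t_obs):
                count += 1
        worst = max(worst, abs(res.p - count / total))
    return worst


def signflip_uniformity(
    seed: int = 0, n_datasets: int = 1000, n: int = 12
) -> float:
    """KS-test p-value of null randomization p-values against uniformity."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        pvals[i] = paired_randomization_test(a, b).p
    return float(sps.kstest(pvals, "uniform").pvalue)


# --------------------------------------------------------------------------
# 6. double-dissociation recovery
# --------------------------------------------------------------------------

def _dissociation_once(seed: int, n_subjects: int, delta: float) -> bool:
    design = GroupDesign(n_subjects=n_subjects, delta=delta)
    cfg = GeneratorConfig(seed=seed)
    data = simulate_group(design, cfg)
    conditions = design.conditions
    planted = data[conditions[0]][0][1].group_templates

    km_subject = KmeansConfig(n_restarts=5, max_iter=50, seed=_sub_seed(seed, 11))
    subject_sets = []
    recordings: dict[str, list[EEGRecording]] = {c: [] for c in conditions}
    for cond in conditions:
        for rec, _ in data[cond]:
            maps = _peak_maps(rec)
            ts, _, _ = modified_kmeans(maps, cfg.n_maps, km_subject)
            subject_sets.append(ts)
            recordings[cond].append(rec)
    pooled = np.vstack([ts.maps for ts in subject_sets])
    meta_k, _, segms = choose_k(
        pooled, 2, 12, KmeansConfig(n_restarts=5, max_iter=50, seed=_sub_seed(seed, 12))
    )
    if meta_k != cfg.n_maps:
        return False
    group_ts = segms[meta_k][0]
    pairs, _ = map_correspondence(planted, group_ts)
    order = {b: a for a, b in pairs}  # recovered id -> planted id

    K = cfg.n_maps
    gevs = np.zeros((n_subjects, 2, K))
    for ci, cond in enumerate(conditions):
        for si, rec in enumerate(recordings[cond]):
            seq = backfit_labels(rec, group_ts)
            g = compute_gev(rec, group_ts, seq)
            for rec_id, planted_id in order.items():
                gevs[si, ci, planted_id - 1] = g[rec_id - 1]

    res = rm_anova_2xk(gevs)
    if not res["interaction"].p_gg < 0.05:
        return False
    # post-hoc: per-map paired comparisons between conditions, Bonferroni
    from .stats import bonferroni_posthoc

    raw_p = np.empty(K)
    diffs = np.empty(K)
    for k in range(K):
        t = sps.ttest_rel(gevs[:, 0, k], gevs[:, 1, k])
        raw_p[k] = t.pvalue
        diffs[k] = float(np.mean(gevs[:, 0, k] - gevs[:, 1, k]))
    p_corr = bonferroni_posthoc(raw_p, K)
    ok3 = p_corr[2] < 0.05 and diffs[2] > 0
    ok4 = p_corr[3] < 0.05 and diffs[3] < 0
    return bool(ok3 and ok4)


def dissociation_recovery(
    seed: int = 0, n_replicates: int = 20, n_subjects: int = 20, delta: float = 0.10
) -> float:
    """Fraction of replicates recovering the planted coverage dissociation.

    The full pipeline runs per replicate: subject clustering, group
    clustering with meta-criterion K selection, back-fitting, 2 x K
    repeated-measures ANOVA and Bonferroni post-hocs; success requires a
    significant condition-by-map interaction and correctly signed,
    significant post-hoc differences on both planted effect maps.
    """
    hits = 0
    for r in range(n_replicates):
        hits += _dissociation_once(_sub_seed(seed, 500 + r), n_subjects, delta)
    return hits / n_replicates


# --------------------------------------------------------------------------
# 7. spectral sanity
# --------------------------------------------------------------------------

def spectral_sanity(seed: int = 0) -> dict[str, float]:
    """Planted delta- vs alpha-carrier states plus analytic tone checks.

    Returns a dict with: ``band_match`` — fraction of planted states whose
    maximal band is their carrier band; ``zero_power_max`` — max power for a
    zero signal; ``tone_peak_freq`` — frequency of the maximal time-averaged
    power bin for a pure 10-Hz tone.
    """
    templates = make_templates(16, 2, seed=_sub_seed(seed, 13))
    cfg = GeneratorConfig(
        n_channels=16, n_maps=2, epoch_length=20.0, snr=np.inf,
        carrier_bands=[(1.0, 4.0), (8.5, 12.0)], mean_duration_ms=500.0,
        seed=_sub_seed(seed, 14),
    )
    rec, gt = simulate_recording(cfg, templates)
    spec_cfg = SpectralConfig()
    tf = morlet_tf(rec, spec_cfg)
    from .backfit import LabelSequence

    seq = LabelSequence(gt.labels, gt.epochs, cfg.sfreq, cfg.n_maps)
    table = band_power_by_microstate(tf, seq, spec_cfg)
    expected = {1: "delta", 2: "alpha"}
    match = np.mean([table.loc[k].idxmax() == band for k, band in expected.items()])

    zero = EEGRecording(np.zeros((4, 4000)), 250.0)
    zero_power = float(np.max(morlet_tf(zero, spec_cfg).power))

    t = np.arange(4000) / 250.0
    tone = np.tile(np.sin(2 * np.pi * 10.0 * t), (4, 1))
    tone[1::2] *= -1  # average-referenced pair structure
    tf_tone = morlet_tf(EEGRecording(tone, 250.0), spec_cfg)
    valid = ~tf_tone.edge
    mean_power = np.array([
        tf_tone.power[:, i, valid[i]].mean() for i in range(len(tf_tone.freqs))
    ])
    tone_peak = float(tf_tone.freqs[int(np.argmax(mean_power))])
    return {
        "band_match": float(match),
        "zero_power_max": zero_power,
        "tone_peak_freq": tone_peak,
    }


# --------------------------------------------------------------------------
# 8. source sanity
# --------------------------------------------------------------------------

def source_sanity(seed: int = 0, n_channels: int = 64, n_points: int = 300,
                  n_subjects: int = 12) -> dict[str, float]:
    """Toy-lead-field localization, thresholding and voxel statistics.

    Returns: ``peak_neighborhood_hit`` (1.0 when the noiseless inverse peak
    for a planted source lies within its 3-nearest-neighborhood),
    ``mask_size_100_q95`` (points retained from 100 distinct values at
    q=95), ``n_significant`` and ``false_positives`` from the paired
    voxelwise randomization with one planted difference.
    """
    rng = np.random.default_rng(_sub_seed(seed, 15))
    lf = toy_leadfield(n_channels, n_points, seed=_sub_seed(seed, 16))
    ecc = np.linalg.norm(lf.positions, axis=1)
    cand = np.flatnonzero((ecc > 0.55) & (ecc < 0.8) & ~lf.degenerate)
    true_pt = int(cand[rng.integers(len(cand))])

    moment = rng.standard_normal(3)
    moment /= np.linalg.norm(moment)
    waveform = np.sin(2 * np.pi * 10 * np.arange(250) / 250.0)
    topo = lf.gain[:, 3 * true_pt: 3 * true_pt + 3] @ moment
    data = np.outer(topo, waveform)
    inv_cfg = InverseConfig(snr=100.0, weighting="none", normalization="resolution")
    est = compute_sources(data, lf, inv_cfg)
    mean_mag = est.magnitudes.mean(axis=1)
    peak = int(np.argmax(mean_mag))
    dists = np.linalg.norm(lf.positions - lf.positions[true_pt], axis=1)
    neighborhood = set(np.argsort(dists)[:4].tolist())  # true point + 3 NN
    hit = float(peak in neighborhood)

    mask100 = percentile_threshold(rng.permutation(100).astype(float), 95.0)
    mask_size = int(mask100.sum())

    # paired voxelwise test: per-subject maps identical between conditions
    # except one planted difference at a retained point
    subject_maps = np.empty((n_subjects, n_points))
    for s in range(n_subjects):
        noisy = data + 0.02 * np.linalg.norm(topo) * rng.standard_normal(data.shape)
        est_s = standardize_sources(compute_sources(noisy, lf, inv_cfg))
        labels = np.ones(est_s.magnitudes.shape[1], dtype=int)
        subject_maps[s] = microstate_source_map(est_s, labels, 1)
    group_mean = subject_maps.mean(axis=0)
    mask = percentile_threshold(group_mean, 95.0)
    retained = np.flatnonzero(mask)
    planted_pt = int(retained[rng.integers(len(retained))])
    maps_b = subject_maps.copy()
    maps_b[:, planted_pt] += group_mean[planted_pt] * (
        0.5 + 0.1 * rng.random(n_subjects))
    sig, _ = voxelwise_randomization(maps_b, subject_maps, mask, alpha=0.005)
    return {
        "peak_neighborhood_hit": hit,
        "mask_size_100_q95": float(mask_size),
        "n_significant": float(sig.sum()),
        "false_positives": float(sig.sum() - bool(sig[planted_pt])),
        "planted_detected": float(bool(sig[planted_pt])),
    }
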