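"""Synthetic multichannel EEG with planted microstate structure.

Emulates the statistical structure that the analysis stages assume, so that
every stage can be validated against a known ground truth:

* a fixed set of well-separated template topographies,
* a piecewise-constant topography sequence with right-skewed sub-second
  segment durations (default gamma, shape 2, mean ~50-100 ms),
* per-state band-limited oscillatory carriers (delta-dominant "sleep",
  alpha/beta "wake"),
* random polarity inversions within segments,
* additive spatially white sensor noise at a configurable SNR,
* per-subject jitter of the group topographies, and
* condition-dependent state coverage (e.g. a planted double dissociation
  between two maps across dream-recall conditions).

State sequences are drawn from a semi-Markov scheme: the jump chain moves
from state ``i`` to ``j != i`` with probability proportional to the target
coverage ``c_j``, which makes state visit frequencies proportional to
``c_i (1 - c_i)``; giving state ``i`` a mean dwell time proportional to
``1 / (1 - c_i)`` then makes the *time* coverage exactly ``c`` in
expectation while the overall mean segment duration stays at the configured
value.  This reproduces a feature of real microstate data: states with more
coverage also dwell longer.

A toy single-sphere lead field (analytic homogeneous-sphere dipole model)
is provided for the source-imaging stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal, special

from .clustering import TemplateSet, _center
from .core import EEGRecording

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "GroupDesign",
    "make_templates",
    "simulate_recording",
    "simulate_group",
    "toy_leadfield",
    "fibonacci_positions",
]

#: Canonical frequency bands (Hz), reused as default carrier choices.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.5, 8.0),
    "alpha": (8.5, 12.0),
    "beta": (12.5, 25.0),
    "gamma": (25.5, 40.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic recording.

    Defaults are the desk-scale analogue of a 30-s-epoch NREM protocol:
    64 channels at 250 Hz, K=5 states with 80-ms mean dwell time, gamma
    (shape 2) durations, delta-band carriers, SNR 2 (an amplitude ratio of
    6 dB between clean signal and sensor noise), and polarity flips with
    probability 0.5 per segment.
    """

    n_channels: int = 64
    sfreq: float = 250.0
    n_maps: int = 5
    epoch_length: float = 30.0
    n_epochs: int = 1
    mean_duration_ms: float = 80.0
    duration_shape: float = 2.0
    carrier_bands: list[tuple[float, float]] | None = None
    carrier_mode: str = "noise"  # "noise" (band-limited) or "tone"
    snr: float = 2.0
    polarity_flip_prob: float = 0.5
    template_max_similarity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maps < 2:
            raise ValueError("need at least 2 maps")
        if not 0.0 <= self.polarity_flip_prob <= 1.0:
            raise ValueError("polarity_flip_prob must lie in [0, 1]")
        if not 0.0 < self.template_max_similarity < 1.0:
            raise ValueError("template_max_similarity must lie in (0, 1)")
        if self.carrier_bands is None:
            self.carrier_bands = [BANDS["delta"]] * self.n_maps
        if len(self.carrier_bands) != self.n_maps:
            raise ValueError("need one carrier band per map")
        fmax = max(hi for _, hi in self.carrier_bands)
        if self.sfreq <= 2 * fmax:
            raise ValueError("sfreq must exceed twice the highest carrier frequency")
        if self.carrier_mode not in ("noise", "tone"):
            raise ValueError("carrier_mode must be 'noise' or 'tone'")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_length * self.sfreq))

    @property
    def mean_duration_samples(self) -> float:
        return self.mean_duration_ms / 1000.0 * self.sfreq


@dataclass
class GroundTruth:
    """Everything that was planted: templates, labels, coverage, carriers."""

    templates: TemplateSet
    labels: np.ndarray              # per-sample map index 1..K
    epochs: np.ndarray
    coverage: np.ndarray            # target per-map time coverage
    carrier_bands: list[tuple[float, float]]
    segment_signs: np.ndarray | None = None
    template_jitter: float | None = None  # |corr| of subject vs group maps

    def realized_coverage(self) -> np.ndarray:
        K = self.templates.n_maps
        counts = np.bincount(self.labels, minlength=K + 1)[1:]
        return counts / len(self.labels)


@dataclass
class GroupDesign:
    """Two-condition group study with a planted coverage dissociation.

    ``effect_maps`` lists (map_id, sign) pairs; condition 1's coverage is
    shifted by ``sign * delta/?`` ... concretely: relative to ``base_coverage``
    the first condition gets ``+delta/2 * sign`` and the second
    ``-delta/2 * sign`` on each effect map, so the between-condition coverage
    difference is exactly ``sign * delta``.
    """

    n_subjects: int = 20
    conditions: tuple[str, str] = ("DE", "NE")
    base_coverage: np.ndarray | None = None
    effect_maps: list[tuple[int, int]] = dc_field(
        default_factory=lambda: [(3, +1), (4, -1)]
    )
    delta: float = 0.10
    subject_jitter: float = 0.9  # target |corr| between subject and group maps

    def condition_coverages(self, K: int) -> tuple[np.ndarray, np.ndarray]:
        base = self.base_coverage
        if base is None:
            base = np.array([0.15, 0.15, 0.25, 0.25, 0.20]) if K == 5 else np.full(K, 1.0 / K)
        base = np.asarray(base, dtype=float)
        if len(base) != K or abs(base.sum() - 1.0) > 1e-9 or np.any(base < 0):
            raise ValueError("base coverage must be a nonnegative length-K vector summing to 1")
        cov_a, cov_b = base.copy(), base.copy()
        for map_id, sign in self.effect_maps:
            shift = 0.5 * self.delta * sign
            cov_a[map_id - 1] += shift
            cov_b[map_id - 1] -= shift
        for cov in (cov_a, cov_b):
            if np.any(cov < 0) or np.any(cov > 1):
                raise ValueError("infeasible delta: coverage leaves [0, 1]")
        return cov_a, cov_b


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------

def make_templates(
    n_channels: int,
    K: int,
    seed: int = 0,
    max_similarity: float = 0.5,
    max_attempts: int = 10_000,
) -> TemplateSet:
    """Draw K random well-separated unit-norm average-referenced maps.

    Rejection sampling: candidate maps are standard-normal vectors,
    average-referenced and normalized; a candidate is kept when its absolute
    spatial correlation with every accepted map is at most
    ``max_similarity``.
    """
    if K >= n_channels:
        raise ValueError("K must be smaller than n_channels")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    attempts = 0
    while len(maps) < K:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {K} maps with |corr| <= {max_similarity} "
                f"in {max_attempts} attempts"
            )
        cand = _center(rng.standard_normal(n_channels))
        cand /= np.linalg.norm(cand)
        if all(abs(float(cand @ m)) <= max_similarity for m in maps):
            maps.append(cand)
    return TemplateSet(np.array(maps), provenance="planted")


def jitter_templates(
    templates: TemplateSet, target_corr: float, rng: np.random.Generator
) -> TemplateSet:
    """Perturb each map so its |corr| with the original is ~``target_corr``.

    Each map is mixed with an average-referenced random direction orthogonal
    to it: ``t' = rho * t + sqrt(1-rho^2) * e``, renormalized.
    """
    if not 0.0 < target_corr <= 1.0:
        raise ValueError("target_corr must lie in (0, 1]")
    out = np.empty_like(templates.maps)
    for k, t in enumerate(templates.maps):
        while True:  # redraw in the measure-zero case e ~ parallel to t
            e = _center(rng.standard_normal(len(t)))
            e -= (e @ t) * t
            n = np.linalg.norm(e)
            if n > 1e-8:
                break
        e /= n
        m = target_corr * t + np.sqrt(1.0 - target_corr**2) * e
        out[k] = m / np.linalg.norm(m)
    return TemplateSet(out, provenance="jittered")


# --------------------------------------------------------------------------
# state sequences and signals
# --------------------------------------------------------------------------

def _state_sequence(
    coverage: np.ndarray,
    n_samples: int,
    mean_dur: float,
    shape: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Semi-Markov label sequence (0-based states) hitting ``coverage``."""
    K = len(coverage)
    c = np.asarray(coverage, dtype=float)
    active = np.flatnonzero(c > 0)
    labels = np.empty(n_samples, dtype=int)
    if len(active) == 1:
        labels[:] = active[0]
        return labels
    ca = c[active]
    # per-state mean dwell (samples): ~ 1/(1-c_i), normalized so the overall
    # visit-weighted mean equals mean_dur
    z = float(np.sum(ca * (1.0 - ca)))
    mean_i = mean_dur * z / (1.0 - ca)
    pos = 0
    state = int(rng.choice(len(active), p=ca))
    while pos < n_samples:
        dur = rng.gamma(shape, mean_i[state] / shape)
        dur = max(2, int(round(dur)))
        end = min(pos + dur, n_samples)
        labels[pos:end] = active[state]
        pos = end
        p = ca.copy()
        p[state] = 0.0
        p /= p.sum()
        state = int(rng.choice(len(active), p=p))
    return labels


def _band_limited_noise(
    n: int, band: tuple[float, float], sfreq: float, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = band
    x = rng.standard_normal(n + 2 * int(sfreq))  # pad to absorb edge transients
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    y = signal.sosfiltfilt(sos, x)[int(sfreq): int(sfreq) + n]
    return y / np.sqrt(np.mean(y**2))


def _tone(n: int, band: tuple[float, float], sfreq: float, rng: np.random.Generator) -> np.ndarray:
    f = 0.5 * (band[0] + band[1])
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / sfreq
    return np.sqrt(2.0) * np.cos(2 * np.pi * f * t + phase)


def simulate_recording(
    config: GeneratorConfig,
    templates: TemplateSet | None = None,
    coverage: np.ndarray | None = None,
    condition: str = "",
) -> tuple[EEGRecording, GroundTruth]:
    """Generate one recording plus its planted ground truth.

    Within a segment the data equal ``template x carrier(t) x sign`` plus
    spatially white sensor noise scaled so the whole-recording RMS ratio of
    clean signal to noise equals ``config.snr``; ``snr=np.inf`` disables the
    noise.  Epochs are generated independently and recorded as boundaries.
    """
    # child stream distinct from the one make_templates(seed) consumes
    rng = np.random.default_rng([config.seed, 1])
    if templates is None:
        templates = make_templates(
            config.n_channels, config.n_maps,
            seed=config.seed, max_similarity=config.template_max_similarity,
        )
    K = templates.n_maps
    if coverage is None:
        coverage = np.full(K, 1.0 / K)
    coverage = np.asarray(coverage, dtype=float)
    if len(coverage) != K:
        raise ValueError("coverage must have one entry per map")
    if abs(coverage.sum() - 1.0) > 1e-8:
        raise ValueError("coverage must sum to 1")

    n_ep, n_s = config.n_epochs, config.epoch_samples
    n_total = n_ep * n_s
    labels = np.empty(n_total, dtype=int)
    clean = np.zeros((config.n_channels, n_total))
    make_carrier = _band_limited_noise if config.carrier_mode == "noise" else _tone
    sign_log: list[int] = []
    for e in range(n_ep):
        o = e * n_s
        lab = _state_sequence(
            coverage, n_s, config.mean_duration_samples, config.duration_shape, rng
        )
        labels[o: o + n_s] = lab
        carriers = np.array(
            [make_carrier(n_s, config.carrier_bands[k], config.sfreq, rng) for k in range(K)]
        )
        # per-segment polarity
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], change, [n_s]])
        for s0, s1 in zip(starts[:-1], starts[1:]):
            k = lab[s0]
            sgn = -1 if rng.random() < config.polarity_flip_prob else 1
            sign_log.append(sgn)
            clean[:, o + s0: o + s1] = (
                sgn * np.outer(templates.maps[k], carriers[k, s0:s1])
            )
    if np.isinf(config.snr):
        data = clean
    else:
        noise = rng.standard_normal(clean.shape)
        rms_sig = np.sqrt(np.mean(clean**2))
        rms_noise = np.sqrt(np.mean(noise**2))
        data = clean + noise * (rms_sig / (config.snr * rms_noise))
    epochs = np.array([[e * n_s, (e + 1) * n_s] for e in range(n_ep)])
    rec = EEGRecording(
        data, config.sfreq,
        ch_pos=fibonacci_positions(config.n_channels),
        epochs=epochs, condition=condition,
        provenance=[f"simulated(seed={config.seed})"],
    )
    gt = GroundTruth(
        templates=templates, labels=labels + 1, epochs=epochs,
        coverage=coverage, carrier_bands=list(config.carrier_bands),
        segment_signs=np.array(sign_log),
    )
    return rec, gt


def simulate_group(
    design: GroupDesign, config: GeneratorConfig
) -> dict[str, list[tuple[EEGRecording, GroundTruth]]]:
    """Simulate ``design.n_subjects`` subjects in both conditions.

    Every subject uses a jittered copy of the shared group templates
    (target |corr| ``design.subject_jitter``); condition coverages differ by
    exactly the planted delta on the designated maps.  Returns a dict
    ``condition -> [(recording, ground_truth), ...]`` ordered by subject.
    """
    # child stream distinct from the one make_templates(seed) consumes
    rng = np.random.default_rng([config.seed, 2])
    group_templates = make_templates(
        config.n_channels, config.n_maps,
        seed=config.seed, max_similarity=config.template_max_similarity,
    )
    cov_a, cov_b = design.condition_coverages(config.n_maps)
    out: dict[str, list[tuple[EEGRecording, GroundTruth]]] = {
        design.conditions[0]: [], design.conditions[1]: [],
    }
    for _ in range(design.n_subjects):
        subj_templates = jitter_templates(group_templates, design.subject_jitter, rng)
        for cond, cov in zip(design.conditions, (cov_a, cov_b)):
            sub_cfg = GeneratorConfig(
                **{**config.__dict__, "seed": int(rng.integers(2**31 - 1))}
            )
            rec, gt = simulate_recording(sub_cfg, subj_templates, cov, condition=cond)
            gt.template_jitter = design.subject_jitter
            gt.group_templates = group_templates  # type: ignore[attr-defined]
            out[cond].append((rec, gt))
    return out


# --------------------------------------------------------------------------
# toy lead field
# --------------------------------------------------------------------------

def fibonacci_positions(n: int, radius: float = 1.0) -> np.ndarray:
    """n roughly uniform sensor positions on a sphere (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sphere_potential(
    electrodes: np.ndarray, source: np.ndarray, n_terms: int = 80, sigma: float = 1.0
) -> np.ndarray:
    """Gain (n_electrodes x 3) of a dipole in a homogeneous unit sphere.

    Series expansion for the surface potential of a current dipole at
    eccentricity b inside a homogeneous conducting sphere with insulating
    exterior:

        V = 1/(4 pi sigma R^2) * sum_n (2n+1)/n * b^(n-1)
            * [ n m_r P_n(cos g) + m_t P_n^1(cos g) ]

    where g is the angle between electrode and source, m_r the radial and
    m_t the in-plane tangential moment component.  Out-of-plane tangential
    moments contribute nothing by symmetry.
    """
    R = 1.0
    b = float(np.linalg.norm(source))
    n_e = len(electrodes)
    e_hat = electrodes / np.linalg.norm(electrodes, axis=1, keepdims=True)
    gain = np.zeros((n_e, 3))
    if b < 1e-12:
        # central dipole: only the n=1 term, radial direction degenerate ->
        # V = 3 (m . e_hat) / (4 pi sigma R^2)
        return 3.0 * e_hat / (4 * np.pi * sigma * R**2)
    s_hat = source / b
    cosg = np.clip(e_hat @ s_hat, -1.0, 1.0)
    sing = np.sqrt(1.0 - cosg**2)
    # tangential in-plane unit vector at each electrode
    t_hat = e_hat - cosg[:, None] * s_hat
    tnorm = np.linalg.norm(t_hat, axis=1)
    ok = tnorm > 1e-12
    t_hat[ok] /= tnorm[ok, None]
    t_hat[~ok] = 0.0
    f = b / R
    coef_r = np.zeros(n_e)
    coef_t = np.zeros(n_e)
    for n in range(1, n_terms + 1):
        pn = special.eval_legendre(n, cosg)
        pn1 = special.lpmv(1, n, cosg)
        scale = (2 * n + 1) / n * f ** (n - 1)
        coef_r += scale * n * pn
        # lpmv uses the Condon-Shortley phase: P_n^1 = -sin(g) dP_n/d(cos g);
        # the tangential term wants +dP_n/dg evaluated along t_hat, which is
        # -P_n^1 under this phase convention
        coef_t += scale * (-pn1)
    pref = 1.0 / (4 * np.pi * sigma * R**2)
    for axis in range(3):
        m = np.zeros(3)
        m[axis] = 1.0
        m_r = float(m @ s_hat)
        m_t = t_hat @ m
        gain[:, axis] = pref * (coef_r * m_r + coef_t * m_t)
    return gain


@dataclass
class LeadField:
    """Gain matrix ``(n_channels, 3 * n_points)`` plus source positions."""

    gain: np.ndarray
    positions: np.ndarray
    electrodes: np.ndarray
    degenerate: np.ndarray | None = None  # mask of near-zero-gain points

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


def toy_leadfield(
    n_channels: int,
    n_sources: int,
    seed: int = 0,
    max_eccentricity: float = 0.85,
) -> LeadField:
    """Analytic single-sphere lead field on random interior source points.

    Electrodes sit on the unit sphere (Fibonacci lattice); sources are drawn
    uniformly in the ball of radius ``max_eccentricity``.  Rows are
    average-referenced (each gain column sums to zero across channels).
    Points whose total gain is near zero are flagged degenerate.
    """
    if n_sources < 1:
        raise ValueError("need at least one source point")
    if not 0 < max_eccentricity < 1:
        raise ValueError("sources must lie strictly inside the sphere")
    rng = np.random.default_rng(seed)
    electrodes = fibonacci_positions(n_channels)
    pts = np.empty((n_sources, 3))
    got = 0
    while got < n_sources:
        cand = rng.uniform(-max_eccentricity, max_eccentricity, size=(n_sources, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= max_eccentricity]
        take = min(len(keep), n_sources - got)
        pts[got: got + take] = keep[:take]
        got += take
    gain = np.empty((n_channels, 3 * n_sources))
    for j, p in enumerate(pts):
        gain[:, 3 * j: 3 * j + 3] = _sphere_potential(electrodes, p)
    gain -= gain.mean(axis=0, keepdims=True)
    col_norm = np.linalg.norm(gain, axis=0).reshape(-1, 3).sum(axis=1)
    degenerate = col_norm < 1e-9 * np.median(col_norm)
    return LeadField(gain, pts, electrodes, degenerate)
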