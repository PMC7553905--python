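# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data validation does and does not show.

## The microstate model

The multichannel EEG `u(t) ∈ R^C` (average-referenced) is modelled as a
sequence of segments during which the scalp topography is proportional to
one of K fixed unit-norm template maps, up to polarity and a time-varying
amplitude. Polarity is never interpreted: oscillating generators invert
the field twice per cycle, so a map and its negation represent the same
state. All similarity computations therefore use the absolute spatial
Pearson correlation `|r|`, and the associated metric
`d = sqrt(2 (1 − |r|))` (the chordal distance between one-dimensional
subspaces of centered map space).

**GFP.** `GFP(t)` is the spatial standard deviation of the
average-referenced map at `t`; its local maxima are the time points of
maximal signal-to-noise topography and are the only samples used for
clustering (full recordings are used for back-fitting). On GFP plateaus
the first sample counts as the peak.

**Modified k-means.** Assignment maximizes `|r|`; the update replaces each
template with the dominant eigenvector of `Σ x̃ x̃ᵀ` over its members
(x̃ = centered raw map). Because `(GFP·r)² = (x̃·t)²/C` for a unit template
t, this update exactly maximizes the cluster's contribution to the Global
Explained Variance, so GEV is non-decreasing over iterations (asserted in
tests). Empty clusters are re-seeded from the worst-fitted map and logged.
Defaults: 100 restarts, 1000 max iterations, GEV tolerance 1e-6; every run
is seeded. Template sign is canonicalized (largest-|entry| channel
positive) purely for reproducibility.

**Cluster-number selection.** The source method names seven validity
indices without formulas; the classical definitions used here are
documented in `microstates/validity.py` next to each implementation
(Baker–Hubert gamma, Rousseeuw silhouette, Davies–Bouldin with the cluster
template as centroid, Milligan–Cooper point-biserial, Dunn with
single-linkage separation and complete diameter, Krzanowski–Lai with
within-dispersion = summed squared distance to the template, and the
predictive-residual cross-validation criterion
`σ² ((C−1)/(C−1−K))²`). All operate on the polarity-invariant metric.
The meta-criterion is the median of the per-index optima; for an even
count the *lower* middle value is taken so the result is an attained,
parsimonious K. Ties within an index break toward smaller K. Indices
undefined at some K (e.g. cross-validation when `C−1−K ≤ 0`, or
Krzanowski–Lai at range edges) are excluded there and logged; `choose_k`
additionally fits K=1 and K=k_max+1 dispersions so Krzanowski–Lai is
defined across the whole requested range.

**Back-fitting and metrics.** Every sample is labelled winner-takes-all
(no correlation threshold, no temporal smoothing by default; both exist as
explicit options and are recorded in provenance). Segments never span
epoch boundaries. Coverage and occurrence use the labelled duration as
denominator; maps with zero presence report duration as missing rather
than zero so group means are not biased. Zero-variance samples receive a
reserved label 0 and are excluded. `Σ_k GEV_k` equals the total GEV of
the labelled fit by construction (exact identity, tested).

## Preprocessing conventions

Order: band-pass → downsample → interpolate → average reference → epoch.
The filter is a 4th-order Butterworth applied forward–backward per epoch
(zero phase, so topographies are not distorted; per-epoch application
avoids bleed across concatenation boundaries). Downsampling is polyphase
with anti-aliasing. Spherical splines follow Perrin (order m=4, Legendre
series to degree 50, ridge 1e-5); the filter family/order is a package
choice recorded in provenance, not a claim about any particular study.
Sample coordinates are 0-based half-open intervals everywhere.

## Spectral analysis

Complex Morlet transform (via mne) on a 1–40 Hz grid at 0.5 Hz. The
mother wavelet is specified by its time-domain FWHM at 1 Hz (default 3 s)
and scales as 1/f, i.e. a constant `n_cycles ≈ 8.0`. The FWHM convention
is exposed as a config knob because toolbox conventions differ. Band
power per microstate averages over the band's bins, all channels and the
map's time points; samples within one wavelet half-width (2.5 σ_t) of an
epoch edge are excluded rather than mirrored, so edge transients cannot
leak into per-state averages. Epochs must exceed the lowest-frequency
wavelet support (≈12.7 s at 1 Hz with the defaults).

## Group statistics

The 2 × K fully within-subject ANOVA uses the classical sums-of-squares
decomposition, each effect tested against its own subject-interaction
error. Greenhouse–Geisser ε is estimated per effect from the
double-centered covariance of the effect's contrast scores and applied
unconditionally (no sphericity pre-test, avoiding data-dependent
branching); uncorrected p is also reported. Partial η² =
SS_eff/(SS_eff+SS_err). Sign-flip randomization: exhaustive enumeration
when `2^n ≤ 4096`, else seeded Monte-Carlo with the add-one rule; the
two-tailed region is `|T*| ≥ |T|` with a 1e-12 relative tie tolerance.
Under a spherical null the GG correction is mildly conservative; the
measured interaction type-I error at n=20 is ≈0.037–0.04 at α=0.05.

## Source imaging

The inverse is a generic distributed weighted minimum norm
`M = W Lᵀ (L W Lᵀ + λI)⁻¹` with depth weighting
`W_p = 1/‖L_p‖²` per point (an optional unweighted mode exists). λ
defaults to `trace(LWLᵀ)/(C · snr²)` with snr = 3. By default each
point's estimated moment is additionally whitened by the inverse square
root of its 3 × 3 resolution-kernel block `[M L]_pp` (sLORETA-style
resolution normalization, `InverseConfig.normalization`); plain minimum
norm has a systematic superficial bias on sparse source grids, while the
resolution-normalized estimate localizes a noiseless single source
exactly — the property the localization checks rely on. Current density is
summarized by the 3-D moment norm (polarity-free, consistent with
polarity-ignored microstates); standardization divides each point's
magnitude course by its own temporal SD (zero-SD points are zeroed and
flagged). Percentile thresholding keeps points *strictly above* the
quantile, so an all-equal map retains nothing. The toy lead field is the
analytic series solution for a current dipole in a homogeneous conducting
sphere (truncated at degree 80, sources at eccentricity ≤ 0.85 for
convergence), with average-referenced rows; a central dipole is handled by
its closed-form limit `3(m·ê)/(4πσR²)`. No head-model computation or
anatomical labelling is attempted.

## The synthetic generator

The generator emulates the statistical structure the analyses assume:
piecewise-constant topographies with right-skewed sub-second dwell times
(gamma, shape 2, truncated at 2 samples; default mean 80 ms), band-limited
oscillatory carriers per state (default delta 1–4 Hz; a pure-tone mode
exists for analytic tests), per-segment polarity flips, spatially white
sensor noise at a configured whole-recording RMS SNR (default amplitude
ratio 2, i.e. 6 dB), per-subject template jitter toward a target
correlation (default 0.9), and condition-dependent state coverage.

State sequences are semi-Markov: from state i the chain jumps to j ≠ i
with probability ∝ target coverage c_j, making visit frequencies
∝ c_i(1−c_i); state i's mean dwell is scaled ∝ 1/(1−c_i), which makes the
expected *time* coverage exactly c while the overall mean dwell stays at
the configured value. A side effect — states with higher coverage also
dwell longer — mirrors the coupling of coverage, duration and explained
variance seen in real microstate data. Degenerate coverages (a single
active state) are special-cased.

Two-condition group designs shift coverage by ±Δ/2 on designated maps
around a base vector (default base `(0.15, 0.15, 0.25, 0.25, 0.20)` for
K=5, Δ=0.10 on maps 3(+) and 4(−)), so the between-condition coverage
difference is exactly ±Δ.

**What passing tests show, and what they do not.** The generator's noise
is spatially white, carriers are stationary within epochs, and templates
are exactly piecewise-constant; real EEG has correlated noise, artifacts,
drifting topographies and no ground truth. Recovery results on this
synthetic data validate the *implementation* (identifiability, polarity
invariance, calibration of the statistics) — they are not evidence about
effect sizes or detectability in recorded sleep EEG.

## Validation problem sizes

The validation experiments run at desk scale, chosen once: 64 channels
(a down-scaled montage), 250 Hz, one 30-s epoch per subject-condition,
20 subjects, K=5, SNR 6 dB, 20 seeded replicates for rate estimates,
1000 simulations for calibration rates, k-means with 5–40 restarts
depending on the stage. The acceptance script reports exactly what these
runs measure; nothing is looked up or hard-coded.

## Known limitations

* No ICA artifact handling, sleep staging or event protocols; an
  epoch-level artifact mask can be applied upstream instead.
* The seven validity indices follow the classical published definitions;
  other toolboxes may implement variants, so the selected K can differ on
  borderline data (the median is robust to one or two divergent indices).
* The spherical toy lead field is a physics-correct but anatomy-free
  stand-in; source results are about operator correctness, not brain
  localization.
* `read_recording` supports EDF via mne and the package's own delimited
  text dialect; other formats should be converted upstream.
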