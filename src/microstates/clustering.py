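"""Microstate template identification.

Pipeline: compute the Global Field Power (GFP) of an average-referenced
recording, keep the scalp maps at GFP local maxima (the time points of
highest signal-to-noise ratio), cluster those maps with a polarity-invariant
modified k-means, and finally cluster the per-subject templates into group
templates.

Polarity is ignored throughout: a map and its negation are the same
microstate, because oscillating generators invert the scalp field twice per
cycle.  Consequently (i) peak maps are assigned to the template with the
largest *absolute* spatial correlation, and (ii) the template update is the
dominant eigenvector of the cluster's outer-product sum rather than a signed
mean, which is invariant to flipping the sign of any subset of member maps.

The quality functional is the Global Explained Variance (GEV): the
GFP^2-weighted fraction of topographic variance explained by assigning each
map to its template.  For a centered map ``x`` and a unit template ``t``,
``(GFP * r)^2 == (x . t)^2 / n_channels``, so the eigenvector update is
exactly the maximizer of the GEV numerator and GEV never decreases across
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EEGRecording

__all__ = [
    "GfpSeries",
    "KmeansConfig",
    "TemplateSet",
    "compute_gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "modified_kmeans",
    "group_cluster",
]


# --------------------------------------------------------------------------
# basic topographic quantities
# --------------------------------------------------------------------------

def _center(maps: np.ndarray) -> np.ndarray:
    """Average-reference map(s): subtract the channel mean (last axis)."""
    maps = np.asarray(maps, dtype=float)
    return maps - maps.mean(axis=-1, keepdims=True)


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two scalp maps across channels.

    Both maps are average-referenced first, so this is the cosine of the
    centered vectors.  The polarity-invariant similarity used everywhere
    else in the package is ``abs(spatial_correlation(a, b))``.

    Raises
    ------
    ZeroDivisionError
        If either map has zero variance across channels (the correlation is
        undefined; callers that can tolerate it must catch this explicitly).
    """
    a = _center(np.asarray(map_a, dtype=float).ravel())
    b = _center(np.asarray(map_b, dtype=float).ravel())
    if a.shape != b.shape:
        raise ValueError("maps must have the same number of channels")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroDivisionError("spatial correlation undefined for a zero-variance map")
    return float(a @ b / (na * nb))


@dataclass
class GfpSeries:
    """Global Field Power per time point, with the recording's epoching."""

    values: np.ndarray
    epochs: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def compute_gfp(recording: EEGRecording) -> GfpSeries:
    """GFP(t) = spatial standard deviation of the map at time t.

    Equivalently the root mean square of the average-referenced map.  The
    recording is average-referenced internally, so a common offset across
    channels does not contribute.
    """
    centered = _center(recording.data.T)  # (n_times, n_channels)
    gfp = np.sqrt(np.mean(centered**2, axis=1))
    return GfpSeries(gfp, recording.epochs.copy(), recording.sfreq)


def find_gfp_peaks(gfp: GfpSeries, min_peak_distance: int = 0) -> np.ndarray:
    """Indices of strict local maxima of the GFP, within epochs only.

    A peak must be strictly greater than both neighbours inside the same
    epoch, so epoch-boundary samples never qualify.  On a plateau the first
    sample counts as the peak (strictly-greater on the right, greater-or-
    equal on the left).  With ``min_peak_distance > 0``, peaks closer than
    that many samples are pruned keeping the larger one (greedy, by height).
    """
    v = gfp.values
    out: list[np.ndarray] = []
    for start, stop in gfp.epochs:
        seg = v[start:stop]
        if len(seg) < 3:
            continue
        left = seg[1:-1] >= seg[:-2]
        strict_left = seg[1:-1] > seg[:-2]
        right = seg[1:-1] > seg[2:]
        # first sample of a plateau: >= on the left, but the plateau must have
        # risen at some point; the simple rule "strictly greater than the
        # previous differing value" reduces to: strictly greater than left
        # neighbour OR (equal to left neighbour and that neighbour is not a
        # peak itself).  For plateaus we keep only indices whose left
        # neighbour is strictly smaller.
        cand = np.flatnonzero(strict_left & right) + start + 1
        # plateau heads: equal on the left are excluded; the head of a
        # plateau has a strictly smaller left neighbour and is caught above
        # provided its right side eventually falls.  Handle flat-then-fall
        # plateaus of length >= 2:
        plateau = np.flatnonzero(strict_left & ~right & left) + 1
        for i in plateau:
            j = i
            while j + 1 < len(seg) and seg[j + 1] == seg[i]:
                j += 1
            if j + 1 < len(seg) and seg[j + 1] < seg[i]:
                cand = np.append(cand, i + start)
        cand.sort()
        out.append(cand)
    peaks = np.concatenate(out) if out else np.empty(0, dtype=int)
    if min_peak_distance > 0 and len(peaks) > 1:
        order = np.argsort(v[peaks])[::-1]  # tallest first
        keep: list[int] = []
        for idx in peaks[order]:
            if all(abs(idx - k) >= min_peak_distance for k in keep):
                keep.append(int(idx))
        peaks = np.array(sorted(keep), dtype=int)
    return peaks


# --------------------------------------------------------------------------
# polarity-invariant modified k-means
# --------------------------------------------------------------------------

@dataclass
class KmeansConfig:
    """Settings for the modified k-means.

    ``tol`` is an absolute tolerance on the GEV improvement between
    iterations; iteration also stops as soon as the assignment is stable.
    """

    n_restarts: int = 100
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class TemplateSet:
    """K microstate template maps (each average-referenced, unit L2 norm).

    ``maps`` has shape ``(K, n_channels)``; map ids are 1..K.  ``gev`` holds
    the per-map GEV on the data the templates were derived from.
    """

    maps: np.ndarray
    provenance: str = ""
    gev: np.ndarray | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise ValueError("maps must be a (K, n_channels) matrix with K >= 1")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n_maps + 1)


def _canonical_sign(t: np.ndarray) -> np.ndarray:
    """Fix the (arbitrary) template sign: largest-|entry| channel positive."""
    i = int(np.argmax(np.abs(t)))
    return -t if t[i] < 0 else t


def _normalize_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and L2-normalize; return (unit maps, original norms)."""
    c = _center(maps)
    norms = np.linalg.norm(c, axis=1)
    unit = np.zeros_like(c)
    ok = norms > 0
    unit[ok] = c[ok] / norms[ok, None]
    return unit, norms


def _gev_from_fit(proj: np.ndarray, norms: np.ndarray) -> float:
    """Total GEV given |x_i . t_{l(i)}| per map and the centered-map norms."""
    denom = float(np.sum(norms**2))
    if denom == 0.0:
        raise ZeroDivisionError("total GFP power is zero")
    return float(np.sum(proj**2) / denom)


def _kmeans_single(
    centered: np.ndarray,
    unit: np.ndarray,
    norms: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    log: list[str],
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    trace: list[float] = []
    n = centered.shape[0]
    init = rng.choice(n, size=K, replace=False)
    templates = unit[init].copy()
    # guard against zero-variance seeds
    for k in range(K):
        while np.linalg.norm(templates[k]) == 0:
            templates[k] = unit[rng.integers(n)]
    labels = np.full(n, -1)
    prev_gev = -np.inf
    for _ in range(max_iter):
        corr = unit @ templates.T          # signed correlation, n x K
        labels_new = np.argmax(np.abs(corr), axis=1)
        fit = np.abs(corr[np.arange(n), labels_new]) * norms
        gev = _gev_from_fit(fit, norms)
        trace.append(gev)
        stable = np.array_equal(labels_new, labels)
        labels = labels_new
        # update templates: dominant eigenvector of sum of outer products of
        # the raw centered member maps (GFP-weighted, sign-invariant)
        for k in range(K):
            members = centered[labels == k]
            if len(members) == 0:
                worst = int(np.argmin(fit))
                templates[k] = unit[worst]
                labels[worst] = k
                log.append(f"empty cluster {k + 1} re-seeded from worst-fit map {worst}")
                continue
            s = members.T @ members
            _, vecs = np.linalg.eigh(s)
            t = vecs[:, -1]
            templates[k] = _canonical_sign(t / np.linalg.norm(t))
        if stable or (gev - prev_gev) < tol and np.isfinite(prev_gev):
            prev_gev = gev
            break
        prev_gev = gev
    corr = unit @ templates.T
    labels = np.argmax(np.abs(corr), axis=1)
    fit = np.abs(corr[np.arange(n), labels]) * norms
    gev = _gev_from_fit(fit, norms)
    trace.append(gev)
    return templates, labels, gev, trace


def modified_kmeans(
    peak_maps: np.ndarray,
    K: int,
    config: KmeansConfig | None = None,
) -> tuple[TemplateSet, np.ndarray, float]:
    """Cluster scalp maps into K polarity-invariant templates.

    Parameters
    ----------
    peak_maps:
        ``(n_maps, n_channels)`` matrix, one GFP-peak map per row.
    K:
        Number of clusters; must not exceed the number of maps.
    config:
        Restart/iteration settings (defaults: 100 restarts, 1000 iterations,
        GEV tolerance 1e-6, seed 0).

    Returns
    -------
    (templates, labels, gev)
        ``templates`` is a :class:`TemplateSet`; ``labels`` the 0-based
        cluster index per input map for the best restart; ``gev`` the total
        GEV of that restart (the max over restarts).
    """
    config = config or KmeansConfig()
    peak_maps = np.asarray(peak_maps, dtype=float)
    if peak_maps.ndim != 2:
        raise ValueError("peak_maps must be 2-D")
    n = peak_maps.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} maps, got {n}")
    centered = _center(peak_maps)
    unit, norms = _normalize_maps(peak_maps)
    rng = np.random.default_rng(config.seed)
    best: tuple[np.ndarray, np.ndarray, float, list[float]] | None = None
    log: list[str] = []
    for _ in range(config.n_restarts):
        t, l, g, tr = _kmeans_single(
            centered, unit, norms, K, rng, config.max_iter, config.tol, log
        )
        if best is None or g > best[2]:
            best = (t, l, g, tr)
    templates, labels, gev, trace = best
    per_map_gev = np.zeros(K)
    corr = unit @ templates.T
    fit2 = (np.abs(corr[np.arange(n), labels]) * norms) ** 2
    denom = float(np.sum(norms**2))
    for k in range(K):
        per_map_gev[k] = np.sum(fit2[labels == k]) / denom
    ts = TemplateSet(templates, provenance="modified_kmeans", gev=per_map_gev, log=log)
    ts.gev_trace = np.asarray(trace)  # per-iteration GEV of the winning restart
    return ts, labels, gev


def group_cluster(
    subject_templates: list[TemplateSet],
    K: int,
    config: KmeansConfig | None = None,
) -> tuple[TemplateSet, np.ndarray, float]:
    """Cluster the pooled per-subject templates into group templates.

    All subjects' template maps are stacked as input samples and passed to
    :func:`modified_kmeans` (each template has unit GFP, so every subject
    map carries equal weight).
    """
    if len(subject_templates) < 2:
        raise ValueError("group clustering needs at least 2 subjects")
    pooled = np.vstack([ts.maps for ts in subject_templates])
    ts, labels, gev = modified_kmeans(pooled, K, config)
    ts.provenance = "group_cluster"
    return ts, labels, gev
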