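"""Cluster-number selection: seven validity criteria and their median.

All criteria operate on the polarity-invariant dissimilarity between scalp
maps, ``d(a, b) = sqrt(2 * (1 - |r(a, b)|))`` with ``r`` the spatial
(Pearson) correlation, so a map and its negation are at distance zero.

The criterion names alone do not pin down formulas; the classical
definitions adopted here are:

* Gamma — Goodman-Kruskal / Baker-Hubert: concordant vs. discordant
  (within, between) distance pairs, (s+ - s-)/(s+ + s-); maximize.
* Silhouette — Rousseeuw's mean silhouette width on the precomputed
  dissimilarity (scikit-learn); maximize.
* Davies-Bouldin — mean over clusters of max_j (S_i + S_j) / M_ij with
  S the mean distance to the cluster template and M the template-template
  distance; minimize.
* Point-biserial — Milligan-Cooper: Pearson correlation between the
  vectorized distance matrix and the 0/1 same/different-cluster indicator;
  maximize.
* Dunn — min single-linkage between-cluster distance over max complete
  within-cluster diameter; maximize.
* Krzanowski-Lai — KL(K) = |DIFF(K)| / |DIFF(K+1)| with
  DIFF(K) = (K-1)^(2/p) W_{K-1} - K^(2/p) W_K, where W is the within-cluster
  dispersion (summed squared dissimilarity to the cluster template) and p
  the map dimensionality; maximize.
* Cross-validation — Pascual-Marqui's predictive residual variance,
  sigma^2 * ((p - 1)/(p - 1 - K))^2; minimize.  Undefined when
  ``p - 1 - K <= 0``.

The meta-criterion is the median of the per-criterion optimal K values; for
an even count the lower middle value is taken (parsimony: the returned K is
always one that some criterion actually attained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

from .clustering import KmeansConfig, TemplateSet, _center, _normalize_maps, modified_kmeans

__all__ = [
    "ValidityProfile",
    "pairwise_dissimilarity",
    "compute_validity_criteria",
    "select_optimal_k",
    "meta_criterion",
    "choose_k",
]

CRITERIA = (
    "gamma",
    "silhouette",
    "davies_bouldin",
    "point_biserial",
    "dunn",
    "krzanowski_lai",
    "cross_validation",
)

#: criteria where larger is better; the rest are minimized
_MAXIMIZE = {"gamma", "silhouette", "point_biserial", "dunn", "krzanowski_lai"}


@dataclass
class ValidityProfile:
    """Per-K criterion values, per-criterion optima and the meta K."""

    k_values: list[int]
    values: dict[str, dict[int, float]]          # criterion -> K -> value
    optima: dict[str, int] = field(default_factory=dict)
    meta_k: int | None = None
    log: list[str] = field(default_factory=list)

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {c: [self.values[c].get(k, np.nan) for k in self.k_values] for c in CRITERIA},
            index=self.k_values,
        )


def pairwise_dissimilarity(maps: np.ndarray) -> np.ndarray:
    """Symmetric polarity-invariant distance matrix, zero diagonal.

    ``d = sqrt(2 (1 - |r|))``; raises on zero-variance maps, for which the
    spatial correlation is undefined.
    """
    unit, norms = _normalize_maps(np.asarray(maps, dtype=float))
    if np.any(norms == 0):
        raise ZeroDivisionError("zero-variance map in dissimilarity computation")
    absr = np.abs(unit @ unit.T)
    np.fill_diagonal(absr, 1.0)
    d = np.sqrt(np.maximum(2.0 * (1.0 - np.minimum(absr, 1.0)), 0.0))
    np.fill_diagonal(d, 0.0)
    return d


# --------------------------------------------------------------------------
# individual criteria (d = precomputed dissimilarity, labels 0-based)
# --------------------------------------------------------------------------

def _within_between(d: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(len(labels), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = d[iu]
    return vals[same], vals[~same]


def _gamma(d: np.ndarray, labels: np.ndarray) -> float:
    w, b = _within_between(d, labels)
    if len(w) == 0 or len(b) == 0:
        return np.nan
    w = np.sort(w)
    # concordant: within < between; discordant: within > between
    s_plus = np.searchsorted(w, b, side="left").sum()
    s_minus = (len(w) - np.searchsorted(w, b, side="right")).sum()
    if s_plus + s_minus == 0:
        return np.nan
    return float((s_plus - s_minus) / (s_plus + s_minus))


def _silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    n_clusters = len(set(labels.tolist()))
    if not 2 <= n_clusters <= len(labels) - 1:
        return np.nan
    return float(silhouette_score(d, labels, metric="precomputed"))


def _template_distances(
    d_to_templates: np.ndarray, labels: np.ndarray, K: int
) -> np.ndarray:
    """Mean distance of each cluster's members to its template."""
    s = np.full(K, np.nan)
    for k in range(K):
        mem = labels == k
        if mem.any():
            s[k] = float(np.mean(d_to_templates[mem, k]))
    return s


def _davies_bouldin(
    d_to_templates: np.ndarray, d_templates: np.ndarray, labels: np.ndarray, K: int
) -> float:
    s = _template_distances(d_to_templates, labels, K)
    if np.any(np.isnan(s)):
        return np.nan
    ratios = np.zeros(K)
    for i in range(K):
        r = [
            (s[i] + s[j]) / d_templates[i, j]
            for j in range(K)
            if j != i and d_templates[i, j] > 0
        ]
        if not r:
            return np.nan
        ratios[i] = max(r)
    return float(np.mean(ratios))


def _point_biserial(d: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(len(labels), k=1)
    vals = d[iu]
    ind = (labels[iu[0]] != labels[iu[1]]).astype(float)
    if ind.std() == 0 or vals.std() == 0:
        return np.nan
    return float(np.corrcoef(vals, ind)[0, 1])


def _dunn(d: np.ndarray, labels: np.ndarray) -> float:
    w, b = _within_between(d, labels)
    if len(b) == 0:
        return np.nan
    diam = w.max() if len(w) else 0.0
    if diam == 0.0:
        return np.inf
    return float(b.min() / diam)


def _dispersion(d_to_templates: np.ndarray, labels: np.ndarray, K: int) -> float:
    """W(K): summed squared dissimilarity of members to their template."""
    idx = np.arange(len(labels))
    return float(np.sum(d_to_templates[idx, labels] ** 2))


def _cross_validation(
    unit: np.ndarray, norms: np.ndarray, templates: np.ndarray, labels: np.ndarray, p: int, K: int
) -> float:
    if p - 1 - K <= 0:
        return np.nan
    proj = np.einsum("ij,ij->i", unit * norms[:, None], templates[labels])
    resid = np.sum(norms**2) - np.sum(proj**2)
    sigma2 = resid / (len(norms) * (p - 1))
    return float(sigma2 * ((p - 1) / (p - 1 - K)) ** 2)


# --------------------------------------------------------------------------
# profile assembly
# --------------------------------------------------------------------------

def compute_validity_criteria(
    peak_maps: np.ndarray,
    segmentations: dict[int, tuple[TemplateSet, np.ndarray]],
    w_extra: dict[int, float] | None = None,
) -> ValidityProfile:
    """Evaluate the seven criteria for every segmentation in ``segmentations``.

    Parameters
    ----------
    peak_maps:
        ``(n_maps, n_channels)`` input maps the segmentations refer to.
    segmentations:
        ``K -> (TemplateSet, labels)`` as produced by modified k-means.
    w_extra:
        Optional extra within-dispersion values ``K -> W(K)`` (e.g. for
        ``K = 1`` or ``K = Kmax + 1``) used only by the Krzanowski-Lai
        ratio at the edges of the tested range.
    """
    maps = np.asarray(peak_maps, dtype=float)
    p = maps.shape[1]
    d = pairwise_dissimilarity(maps)
    unit, norms = _normalize_maps(maps)
    ks = sorted(segmentations)
    values: dict[str, dict[int, float]] = {c: {} for c in CRITERIA}
    log: list[str] = []

    disp: dict[int, float] = dict(w_extra or {})
    d_to_templates_by_k: dict[int, np.ndarray] = {}
    for K in ks:
        ts, labels = segmentations[K]
        t_unit, _ = _normalize_maps(ts.maps)
        absr = np.abs(unit @ t_unit.T)
        d_to_templates = np.sqrt(np.maximum(2.0 * (1.0 - np.minimum(absr, 1.0)), 0.0))
        d_to_templates_by_k[K] = d_to_templates
        disp[K] = _dispersion(d_to_templates, labels, K)

    degenerate_input = bool(np.allclose(d, 0.0))
    for K in ks:
        ts, labels = segmentations[K]
        t_unit, _ = _normalize_maps(ts.maps)
        d_templates = np.sqrt(
            np.maximum(2.0 * (1.0 - np.minimum(np.abs(t_unit @ t_unit.T), 1.0)), 0.0)
        )
        dt = d_to_templates_by_k[K]
        if degenerate_input:
            # all maps identical (up to polarity): silhouette 0 by convention
            values["silhouette"][K] = 0.0
            log.append(f"K={K}: degenerate (all maps identical); silhouette set to 0")
        else:
            values["silhouette"][K] = _silhouette(d, labels)
        values["gamma"][K] = _gamma(d, labels)
        values["davies_bouldin"][K] = _davies_bouldin(dt, d_templates, labels, K)
        values["point_biserial"][K] = _point_biserial(d, labels)
        values["dunn"][K] = _dunn(d, labels)
        values["cross_validation"][K] = _cross_validation(
            unit, norms, _normalize_maps(ts.maps)[0], labels, p, K
        )
    # Krzanowski-Lai needs W at K-1 and K+1
    def diff(K: int) -> float:
        if K - 1 not in disp or K not in disp:
            return np.nan
        return (K - 1) ** (2.0 / p) * disp[K - 1] - K ** (2.0 / p) * disp[K]

    for K in ks:
        d_k, d_k1 = diff(K), diff(K + 1)
        if np.isnan(d_k) or np.isnan(d_k1) or d_k1 == 0.0:
            values["krzanowski_lai"][K] = np.nan
        else:
            values["krzanowski_lai"][K] = abs(d_k) / abs(d_k1)
    return ValidityProfile(ks, values, log=log)


def select_optimal_k(profile: ValidityProfile) -> dict[str, int]:
    """Per-criterion optimal K (ties broken toward smaller K)."""
    optima: dict[str, int] = {}
    for c in CRITERIA:
        vals = profile.values.get(c, {})
        finite = {k: v for k, v in vals.items() if np.isfinite(v)}
        if not finite:
            profile.log.append(f"criterion {c} undefined at every K; excluded")
            continue
        ks = sorted(finite)
        arr = np.array([finite[k] for k in ks])
        if c not in _MAXIMIZE:
            arr = -arr
        optima[c] = ks[int(np.argmax(arr))]  # argmax returns first max -> smaller K
    profile.optima = optima
    return optima


def meta_criterion(optima: dict[str, int] | list[int]) -> int:
    """Median of the per-criterion optima; even count -> lower middle."""
    vals = sorted(optima.values() if isinstance(optima, dict) else optima)
    if not vals:
        raise ValueError("no defined criterion optima")
    return int(vals[(len(vals) - 1) // 2])


def choose_k(
    peak_maps: np.ndarray,
    k_min: int = 2,
    k_max: int = 12,
    config: KmeansConfig | None = None,
) -> tuple[int, ValidityProfile, dict[int, tuple[TemplateSet, np.ndarray]]]:
    """Run k-means over a K range and pick K by the meta-criterion.

    Also fits K = 1 and K = k_max + 1 (dispersion only) so the
    Krzanowski-Lai ratio is defined over the whole tested range.
    """
    config = config or KmeansConfig()
    maps = np.asarray(peak_maps, dtype=float)
    segmentations: dict[int, tuple[TemplateSet, np.ndarray]] = {}
    w_extra: dict[int, float] = {}
    unit, norms = _normalize_maps(maps)
    # K = 1: single dominant eigenvector
    centered = _center(maps)
    s = centered.T @ centered
    _, vecs = np.linalg.eigh(s)
    t1 = vecs[:, -1:]
    absr = np.abs(unit @ (t1 / np.linalg.norm(t1)))
    d1 = np.sqrt(np.maximum(2.0 * (1.0 - np.minimum(absr, 1.0)), 0.0))
    w_extra[1] = float(np.sum(d1**2))
    upper = min(k_max + 1, len(maps))
    for K in range(k_min, upper + 1):
        ts, labels, _ = modified_kmeans(maps, K, config)
        if K <= k_max:
            segmentations[K] = (ts, labels)
        else:
            t_unit, _ = _normalize_maps(ts.maps)
            absr = np.abs(unit @ t_unit.T)
            dt = np.sqrt(np.maximum(2.0 * (1.0 - np.minimum(absr, 1.0)), 0.0))
            w_extra[K] = _dispersion(dt, labels, K)
    profile = compute_validity_criteria(maps, segmentations, w_extra)
    optima = select_optimal_k(profile)
    profile.meta_k = meta_criterion(optima)
    return profile.meta_k, profile, segmentations
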