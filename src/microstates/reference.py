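"""Naive reference implementations for validation.

Deliberately slow, loop-based re-derivations of the package's topographic
and cluster-validity quantities, written directly from their definitions
and sharing no code with the optimized implementations.  They exist to be
compared against on small instances (tens of maps, hundreds of samples);
never use them on real-sized data.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "gfp_naive",
    "pearson_naive",
    "dissimilarity_naive",
    "gev_naive",
    "segment_stats_naive",
    "gamma_naive",
    "silhouette_naive",
    "davies_bouldin_naive",
    "point_biserial_naive",
    "dunn_naive",
    "dispersion_naive",
    "krzanowski_lai_naive",
    "cross_validation_naive",
]


def gfp_naive(data: np.ndarray) -> np.ndarray:
    """Spatial standard deviation per time point (columns of channels x time)."""
    out = []
    for t in range(data.shape[1]):
        col = data[:, t]
        out.append(math.sqrt(np.mean((col - col.mean()) ** 2)))
    return np.array(out)


def pearson_naive(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / math.sqrt(np.sum(am**2) * np.sum(bm**2)))


def dissimilarity_naive(maps: np.ndarray) -> np.ndarray:
    n = len(maps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = abs(pearson_naive(maps[i], maps[j]))
            d[i, j] = d[j, i] = math.sqrt(2 * (1 - min(r, 1.0)))
    return d


def gev_naive(data: np.ndarray, templates: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-map GEV by direct summation: sum_(t in k) (GFP_t r_t)^2 / sum_t GFP_t^2."""
    n_ch, n_t = data.shape
    gfp = gfp_naive(data)
    denom = float(np.sum(gfp**2))
    K = templates.shape[0]
    gev = np.zeros(K)
    for t in range(n_t):
        k = labels[t]
        if k == 0:
            continue
        r = pearson_naive(data[:, t], templates[k - 1])
        gev[k - 1] += (gfp[t] * r) ** 2
    return gev / denom


def segment_stats_naive(labels: np.ndarray, epochs: np.ndarray, sfreq: float, n_maps: int):
    """(mean_duration_ms, occurrence_hz, coverage) per map, cutting at epochs."""
    runs: dict[int, list[int]] = {k: [] for k in range(1, n_maps + 1)}
    for a, b in epochs:
        t = a
        while t < b:
            k = labels[t]
            length = 0
            while t < b and labels[t] == k:
                t += 1
                length += 1
            if k != 0:
                runs[k].append(length)
    labeled = int(np.sum(labels != 0))
    secs = labeled / sfreq
    dur = np.array([np.mean(runs[k]) * 1000 / sfreq if runs[k] else np.nan
                    for k in range(1, n_maps + 1)])
    occ = np.array([len(runs[k]) / secs if secs else 0.0 for k in range(1, n_maps + 1)])
    cov = np.array([sum(runs[k]) / labeled if labeled else 0.0 for k in range(1, n_maps + 1)])
    return dur, occ, cov


# --------------------------------------------------------------------------
# validity criteria, straight from the definitions
# --------------------------------------------------------------------------

def _pairs(d: np.ndarray, labels: np.ndarray):
    within, between = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(d[i, j])
    return within, between


def gamma_naive(d: np.ndarray, labels: np.ndarray) -> float:
    within, between = _pairs(d, labels)
    s_plus = s_minus = 0
    for w in within:
        for b in between:
            if w < b:
                s_plus += 1
            elif w > b:
                s_minus += 1
    return (s_plus - s_minus) / (s_plus + s_minus)


def silhouette_naive(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        bs = []
        for c in set(labels.tolist()) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            bs.append(np.mean([d[i, j] for j in other]))
        b = min(bs)
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def davies_bouldin_naive(d_to_templates: np.ndarray, d_templates: np.ndarray,
                         labels: np.ndarray) -> float:
    K = d_templates.shape[0]
    s = [np.mean([d_to_templates[i, k] for i in range(len(labels)) if labels[i] == k])
         for k in range(K)]
    total = 0.0
    for i in range(K):
        total += max((s[i] + s[j]) / d_templates[i, j] for j in range(K) if j != i)
    return total / K


def point_biserial_naive(d: np.ndarray, labels: np.ndarray) -> float:
    within, between = _pairs(d, labels)
    x = np.array(within + between)
    y = np.array([0.0] * len(within) + [1.0] * len(between))
    return pearson_naive(x, y)


def dunn_naive(d: np.ndarray, labels: np.ndarray) -> float:
    within, between = _pairs(d, labels)
    return min(between) / max(within)


def dispersion_naive(d_to_templates: np.ndarray, labels: np.ndarray) -> float:
    return float(sum(d_to_templates[i, labels[i]] ** 2 for i in range(len(labels))))


def krzanowski_lai_naive(w: dict[int, float], K: int, p: int) -> float:
    def diff(k: int) -> float:
        return (k - 1) ** (2.0 / p) * w[k - 1] - k ** (2.0 / p) * w[k]

    return abs(diff(K)) / abs(diff(K + 1))


def cross_validation_naive(maps: np.ndarray, templates: np.ndarray,
                           labels: np.ndarray) -> float:
    n, p = maps.shape
    K = templates.shape[0]
    resid = 0.0
    for i in range(n):
        x = maps[i] - maps[i].mean()
        t = templates[labels[i]] - templates[labels[i]].mean()
        t = t / np.linalg.norm(t)
        resid += float(x @ x) - float(x @ t) ** 2
    sigma2 = resid / (n * (p - 1))
    return sigma2 * ((p - 1) / (p - 1 - K)) ** 2
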