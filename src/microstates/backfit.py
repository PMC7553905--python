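"""Winner-takes-all back-fitting and per-microstate temporal metrics.

Every time point of a recording is labelled with the template of highest
absolute spatial correlation; maximal runs of one label (within an epoch)
are the microstate segments from which mean duration, occurrence and
coverage are computed, and the GFP^2-weighted explained variance (GEV)
quantifies how much of the topographic variance each template accounts for.

Labels use map ids 1..K; the reserved id 0 marks zero-variance time points,
which are excluded from all metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import TemplateSet, _center, _normalize_maps
from .core import EEGRecording

__all__ = [
    "LabelSequence",
    "backfit_labels",
    "segment_statistics",
    "compute_gev",
    "metrics_table",
    "map_correspondence",
]

UNDEFINED = 0  # reserved label for zero-variance samples


@dataclass
class LabelSequence:
    """Per-timepoint winner map index (1..K; 0 = undefined), epoch-aware."""

    labels: np.ndarray
    epochs: np.ndarray
    sfreq: float
    n_maps: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.epochs = np.asarray(self.epochs, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.epochs[-1, 1] != len(self.labels):
            raise ValueError("labels length must match the epoch span")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) > self.n_maps:
            raise ValueError("label outside 0..K")

    def runs(self):
        """Yield (map_id, start, stop) for every maximal run within an epoch."""
        for a, b in self.epochs:
            seg = self.labels[a:b]
            change = np.flatnonzero(np.diff(seg)) + 1
            starts = np.concatenate([[0], change])
            stops = np.concatenate([change, [len(seg)]])
            for s, e in zip(starts, stops):
                yield int(seg[s]), a + int(s), a + int(e)


def backfit_labels(
    recording: EEGRecording,
    templates: TemplateSet,
    min_abs_corr: float = 0.0,
    smooth_min_samples: int = 0,
) -> LabelSequence:
    """Label every sample with the best template by absolute correlation.

    Ties are broken toward the lowest map id.  ``min_abs_corr`` optionally
    rejects samples whose best |correlation| falls below the threshold
    (labelled 0); default 0 labels everything.  ``smooth_min_samples``
    optionally merges runs shorter than that many samples into the
    neighbouring run with the higher adjacent correlation (off by default).
    """
    x = _center(recording.data.T)
    norms = np.linalg.norm(x, axis=1)
    t_unit, _ = _normalize_maps(templates.maps)
    ok = norms > 0
    absr = np.zeros((len(x), templates.n_maps))
    absr[ok] = np.abs((x[ok] / norms[ok, None]) @ t_unit.T)
    labels = np.where(ok, np.argmax(absr, axis=1) + 1, UNDEFINED)
    if min_abs_corr > 0:
        best = absr[np.arange(len(x)), np.clip(labels - 1, 0, None)]
        labels = np.where(best >= min_abs_corr, labels, UNDEFINED)
    seq = LabelSequence(labels, recording.epochs.copy(), recording.sfreq, templates.n_maps)
    if smooth_min_samples > 1:
        seq = _merge_short_runs(seq, absr, smooth_min_samples)
    return seq


def _merge_short_runs(seq: LabelSequence, absr: np.ndarray, min_len: int) -> LabelSequence:
    labels = seq.labels.copy()
    for a, b in seq.epochs:
        changed = True
        while changed:
            changed = False
            for map_id, s, e in LabelSequence(labels, seq.epochs, seq.sfreq, seq.n_maps).runs():
                if not (a <= s and e <= b) or map_id == UNDEFINED or e - s >= min_len:
                    continue
                left = labels[s - 1] if s > a else None
                right = labels[e] if e < b else None
                cand = [c for c in (left, right) if c not in (None, UNDEFINED)]
                if not cand:
                    continue
                scores = {c: absr[s:e, c - 1].mean() for c in set(cand)}
                labels[s:e] = max(scores, key=scores.get)
                changed = True
                break
    return LabelSequence(labels, seq.epochs, seq.sfreq, seq.n_maps)


def segment_statistics(seq: LabelSequence) -> pd.DataFrame:
    """Mean duration (ms), occurrence (1/s) and coverage per map.

    A segment is a maximal run of one label inside one epoch.  The
    occurrence/coverage denominator is the total labelled (non-undefined)
    duration.  Maps never present get duration NaN (missing, not zero),
    occurrence 0 and coverage 0.
    """
    run_lengths: dict[int, list[int]] = {k: [] for k in range(1, seq.n_maps + 1)}
    for map_id, s, e in seq.runs():
        if map_id != UNDEFINED:
            run_lengths[map_id].append(e - s)
    labeled_samples = int(np.sum(seq.labels != UNDEFINED))
    labeled_seconds = labeled_samples / seq.sfreq
    rows = []
    for k in range(1, seq.n_maps + 1):
        lens = run_lengths[k]
        n_samples = sum(lens)
        rows.append(
            {
                "map": k,
                "mean_duration_ms": (np.mean(lens) * 1000.0 / seq.sfreq) if lens else np.nan,
                "occurrence_hz": len(lens) / labeled_seconds if labeled_seconds else 0.0,
                "coverage": n_samples / labeled_samples if labeled_samples else 0.0,
            }
        )
    return pd.DataFrame(rows)


def compute_gev(
    recording: EEGRecording, templates: TemplateSet, seq: LabelSequence
) -> np.ndarray:
    """Per-map GEV: sum_{t labelled k} (GFP_t r_t)^2 / sum_t GFP_t^2.

    ``r_t`` is the spatial correlation between the sample map at ``t`` and
    template ``k``; the denominator runs over all time points.  The sum over
    maps equals the total GEV of the labelled fit.
    """
    x = _center(recording.data.T)
    norms = np.linalg.norm(x, axis=1)
    denom = float(np.sum(norms**2))
    if denom == 0.0:
        raise ZeroDivisionError("zero total GFP power")
    t_unit, _ = _normalize_maps(templates.maps)
    gev = np.zeros(templates.n_maps)
    for k in range(1, templates.n_maps + 1):
        mask = seq.labels == k
        if not mask.any():
            continue
        proj = x[mask] @ t_unit[k - 1]  # = gfp * r * sqrt(n_ch); squared ratios cancel
        gev[k - 1] = float(np.sum(proj**2) / denom)
    return gev


def metrics_table(
    recording: EEGRecording,
    templates: TemplateSet,
    seq: LabelSequence,
    subject: str = "",
    condition: str | None = None,
) -> pd.DataFrame:
    """Tidy per-(subject, condition, map) metrics: GEV + segment statistics."""
    stats = segment_statistics(seq)
    stats.insert(0, "subject", subject)
    stats.insert(1, "condition", condition if condition is not None else recording.condition)
    stats["gev"] = compute_gev(recording, templates, seq)
    return stats


def map_correspondence(
    templates_a: TemplateSet, templates_b: TemplateSet
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Optimal one-to-one matching of two template sets.

    Maximizes the summed absolute spatial correlation (Hungarian algorithm)
    and returns ``(pairs, table)`` where ``pairs`` holds 1-based
    ``(id_a, id_b)`` matches and ``table`` the full |corr| matrix
    (rows = set a, columns = set b).  With unequal K the best partial
    matching is returned with a warning.
    """
    ua, _ = _normalize_maps(templates_a.maps)
    ub, _ = _normalize_maps(templates_b.maps)
    table = np.abs(ua @ ub.T)
    if templates_a.n_maps != templates_b.n_maps:
        import warnings

        warnings.warn("template sets of unequal size; best partial matching")
    rows, cols = linear_sum_assignment(-table)
    pairs = [(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)]
    return pairs, table
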