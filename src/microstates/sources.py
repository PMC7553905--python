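"""Simplified distributed source imaging for microstate maps.

A generic weighted-minimum-norm linear inverse is built from a supplied
lead field (e.g. the analytic single-sphere toy lead field in
:mod:`microstates.synthetic`):

    M = W L^T (L W L^T + lambda C)^{-1}

with ``W`` a diagonal source weighting (default: depth weighting by inverse
squared column norm per point), ``C`` the identity noise covariance, and
``lambda`` either fixed or set from an SNR rule
``lambda = trace(L W L^T) / (n_channels * snr^2)``.  This is a generic
distributed inverse; no claim is made to reproduce any particular
vendor-specific operator.

An optional resolution normalization (sLORETA-style) whitens each point's
estimated moment by the inverse square root of its 3 x 3 resolution-kernel
block ``[M L]_pp``.  For a noiseless single source this normalization has
zero localization error, which plain (weighted) minimum norm does not
guarantee on a sparse source grid; it is the default for localization.

Downstream: current density is summarized per point by the norm of the 3-D
moment (polarity-free), each point's time course is divided by its own
temporal standard deviation to remove activation biases, labelled time
points are averaged per microstate, group maps are thresholded at a
percentile (strictly above), and retained points are compared between
conditions with paired sign-flip randomization tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import paired_randomization_test
from .synthetic import LeadField

__all__ = [
    "InverseConfig",
    "SourceEstimate",
    "build_inverse_operator",
    "resolution_whitener",
    "apply_inverse",
    "compute_sources",
    "standardize_sources",
    "microstate_source_map",
    "percentile_threshold",
    "voxelwise_randomization",
]


@dataclass
class InverseConfig:
    """Regularization and weighting choices for the linear inverse."""

    lam: float | str = "auto"   # nonnegative scalar, or "auto" for the SNR rule
    snr: float = 3.0
    weighting: str = "depth"    # "depth" | "none"
    normalization: str = "resolution"  # "resolution" (sLORETA-style) | "none"
    standardize: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.lam, (int, float)) and self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.weighting not in ("depth", "none"):
            raise ValueError("weighting must be 'depth' or 'none'")
        if self.normalization not in ("resolution", "none"):
            raise ValueError("normalization must be 'resolution' or 'none'")


@dataclass
class SourceEstimate:
    """Per-point current-density magnitudes over time, ``(n_points, n_times)``."""

    magnitudes: np.ndarray
    positions: np.ndarray
    standardized: bool = False
    degenerate: np.ndarray | None = None  # points with zero temporal SD

    @property
    def n_points(self) -> int:
        return self.magnitudes.shape[0]


def build_inverse_operator(
    leadfield: LeadField, config: InverseConfig | None = None
) -> np.ndarray:
    """Weighted-minimum-norm operator mapping channel maps to 3-D moments.

    The operator annihilates a common offset across channels (average-
    reference consistency) because the average-referenced lead-field columns
    make ``L^T 1 = 0``.
    """
    config = config or InverseConfig()
    l = np.asarray(leadfield.gain, dtype=float)
    n_ch, n_cols = l.shape
    if n_cols % 3:
        raise ValueError("gain must have 3 columns per source point")
    if config.weighting == "depth":
        col_norm2 = np.sum(l**2, axis=0).reshape(-1, 3).sum(axis=1)
        floor = 1e-12 * max(float(col_norm2.max()), 1.0)
        w = np.repeat(1.0 / np.maximum(col_norm2, floor), 3)
    else:
        w = np.ones(n_cols)
    lw = l * w[None, :]
    gram = lw @ l.T
    if config.lam == "auto":
        lam = float(np.trace(gram)) / (n_ch * config.snr**2)
    else:
        lam = float(config.lam)
    a = gram + lam * np.eye(n_ch)
    try:
        inv = np.linalg.inv(a)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular system: lambda=0 with a rank-deficient lead field"
        ) from err
    return lw.T @ inv


def resolution_whitener(leadfield: LeadField, operator: np.ndarray) -> np.ndarray:
    """Per-point inverse square root of the 3x3 resolution-kernel block.

    For point ``p``, the block is ``R_pp = operator_p @ L_p``; the returned
    ``(n_points, 3, 3)`` array holds symmetric whiteners ``R_pp^{-1/2}``
    (eigenvalues floored at 1e-12 of the block maximum for stability), so
    that ``|R_pp^{-1/2} m_p|^2 = m_p^T R_pp^{-1} m_p`` — the sLORETA-style
    standardized power.
    """
    l = leadfield.gain
    n_points = l.shape[1] // 3
    out = np.empty((n_points, 3, 3))
    for p in range(n_points):
        block = operator[3 * p: 3 * p + 3] @ l[:, 3 * p: 3 * p + 3]
        s = 0.5 * (block + block.T)
        vals, vecs = np.linalg.eigh(s)
        floor = 1e-12 * max(float(vals.max()), 1e-300)
        vals = np.maximum(vals, floor)
        out[p] = (vecs / np.sqrt(vals)) @ vecs.T
    return out


def apply_inverse(
    data: np.ndarray,
    operator: np.ndarray,
    positions: np.ndarray,
    whitener: np.ndarray | None = None,
) -> SourceEstimate:
    """Apply the operator to ``(n_channels, n_times)`` data; return magnitudes.

    With ``whitener`` (from :func:`resolution_whitener`) each point's moment
    is resolution-whitened before taking the norm.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    moments = operator @ data                      # (3P, T)
    p = moments.shape[0] // 3
    moments = moments.reshape(p, 3, -1)
    if whitener is not None:
        moments = np.einsum("pij,pjt->pit", whitener, moments)
    mags = np.linalg.norm(moments, axis=1)
    return SourceEstimate(mags, np.asarray(positions))


def compute_sources(
    data: np.ndarray, leadfield: LeadField, config: InverseConfig | None = None
) -> SourceEstimate:
    """Operator construction + (optional) resolution normalization + apply."""
    config = config or InverseConfig()
    op = build_inverse_operator(leadfield, config)
    whitener = (
        resolution_whitener(leadfield, op)
        if config.normalization == "resolution" else None
    )
    return apply_inverse(data, op, leadfield.positions, whitener)


def standardize_sources(estimate: SourceEstimate) -> SourceEstimate:
    """Divide each point's magnitude time course by its temporal SD.

    Points with zero temporal SD are set to zero and flagged degenerate.
    The result is scale invariant: scaling the input data by any positive
    constant leaves the standardized estimate unchanged.
    """
    mags = estimate.magnitudes
    if mags.shape[1] < 2:
        raise ValueError("standardization needs at least 2 time points")
    sd = mags.std(axis=1, ddof=0)
    out = np.zeros_like(mags)
    ok = sd > 0
    out[ok] = mags[ok] / sd[ok, None]
    return SourceEstimate(
        out, estimate.positions, standardized=True, degenerate=~ok
    )


def microstate_source_map(
    estimate: SourceEstimate, labels: np.ndarray, map_id: int
) -> np.ndarray:
    """Mean (standardized) magnitude over the time points labelled ``map_id``.

    Returns an ``(n_points,)`` vector; all-NaN when the map has zero
    presence (missing, not zero).
    """
    labels = np.asarray(labels)
    if len(labels) != estimate.magnitudes.shape[1]:
        raise ValueError("labels and source estimate are not aligned")
    sel = labels == map_id
    if not sel.any():
        return np.full(estimate.n_points, np.nan)
    return estimate.magnitudes[:, sel].mean(axis=1)


def percentile_threshold(group_mean_map: np.ndarray, q: float = 95.0) -> np.ndarray:
    """Mask of points strictly above the q-th percentile of the mean map.

    With all values equal the mask is empty (strictly-above convention).
    """
    if not 0 < q < 100:
        raise ValueError("q must lie in (0, 100)")
    v = np.asarray(group_mean_map, dtype=float)
    return v > np.percentile(v, q)


def voxelwise_randomization(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.005,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired sign-flip test per retained point; uncorrected threshold.

    ``maps_a``/``maps_b`` are ``(n_subjects, n_points)`` per-subject source
    maps of the two conditions (or microstates).  Returns
    ``(significant_mask, p_values)`` over all points; points outside
    ``mask`` get p = NaN and are never significant.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape or maps_a.ndim != 2:
        raise ValueError("need matching (n_subjects, n_points) map stacks")
    mask = np.asarray(mask, dtype=bool)
    p = np.full(maps_a.shape[1], np.nan)
    for j in np.flatnonzero(mask):
        res = paired_randomization_test(
            maps_a[:, j], maps_b[:, j], n_perm=n_perm, seed=seed + j
        )
        p[j] = res.p
    sig = np.zeros(maps_a.shape[1], dtype=bool)
    sig[mask] = p[mask] < alpha
    return sig, p
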