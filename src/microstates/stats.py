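"""Group-level statistics for microstate metrics.

* :func:`rm_anova_2xk` — fully within-subject 2 x K ANOVA (condition x
  microstate class) with the classical sums-of-squares decomposition, each
  effect tested against its own subject-interaction error term.  The
  Greenhouse-Geisser epsilon is estimated per effect from the covariance of
  the effect's contrast scores and applied unconditionally (no sphericity
  pre-test); partial eta^2 = SS_effect / (SS_effect + SS_error).
* :func:`bonferroni_posthoc` — p_corr = min(1, m * p).
* :func:`paired_randomization_test` — two-tailed sign-flip test of the mean
  paired difference; exhaustive enumeration of all 2^n sign patterns when
  2^n <= 4096, seeded Monte-Carlo with the add-one rule otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "RandomizationResult",
    "rm_anova_2xk",
    "bonferroni_posthoc",
    "paired_randomization_test",
]

EXHAUSTIVE_LIMIT = 4096  # enumerate all sign patterns when 2^n <= this


@dataclass
class AnovaResult:
    effect: str
    f: float
    df1: float
    df2: float
    p: float
    epsilon: float
    p_gg: float
    partial_eta2: float


@dataclass
class RandomizationResult:
    statistic: float
    p: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    degenerate: bool = False


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x level contrast scores."""
    k = scores.shape[1]
    if k < 2:
        return 1.0
    s = np.cov(scores, rowvar=False, ddof=1)
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    st = h @ s @ h
    tr = np.trace(st)
    denom = (k - 1) * float(np.sum(st * st))
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova_2xk(data: np.ndarray) -> dict[str, AnovaResult]:
    """Two-way fully repeated-measures ANOVA on ``(n_subjects, 2, K)`` data.

    Returns results for the effects ``"condition"``, ``"map"`` and
    ``"interaction"``.  Requires a complete balanced design with at least
    three subjects; a zero error variance raises (degenerate input).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3 or y.shape[1] != 2:
        raise ValueError("data must have shape (n_subjects, 2, K)")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells in the design")
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_as - ss_bs - ss_s

    effects = {
        "condition": (ss_a, a - 1, ss_as, (a - 1) * (n - 1), m_as),
        "map": (ss_b, b - 1, ss_bs, (b - 1) * (n - 1), m_bs),
        "interaction": (ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1),
                        y[:, 0, :] - y[:, 1, :]),
    }
    out: dict[str, AnovaResult] = {}
    for name, (ss_eff, df1, ss_err, df2, scores) in effects.items():
        if ss_err <= 0:
            raise ZeroDivisionError(f"zero error variance for effect {name!r}")
        f = (ss_eff / df1) / (ss_err / df2)
        p = float(sps.f.sf(f, df1, df2))
        eps = _gg_epsilon(np.asarray(scores))
        p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
        out[name] = AnovaResult(
            effect=name, f=float(f), df1=float(df1), df2=float(df2), p=p,
            epsilon=eps, p_gg=p_gg,
            partial_eta2=float(ss_eff / (ss_eff + ss_err)),
        )
    return out


def bonferroni_posthoc(p_values: np.ndarray | list[float], m: int | None = None) -> np.ndarray:
    """Bonferroni correction: ``min(1, m * p)`` (default m = number of tests)."""
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def paired_randomization_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = 0,
) -> RandomizationResult:
    """Two-tailed sign-flip test of the mean paired difference.

    The observed statistic is ``mean(a - b)``; the null distribution flips
    the sign of each paired difference independently.  All ``2^n`` patterns
    are enumerated when ``2^n <= 4096`` (exact proportion); otherwise
    ``n_perm`` seeded random patterns are drawn and the add-one rule
    ``p = (count + 1) / (n_perm + 1)`` avoids p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired 1-D samples, n >= 2")
    d = a - b
    n = len(d)
    t_obs = float(d.mean())
    if np.all(d == 0):
        return RandomizationResult(0.0, 1.0, 0, True, seed, degenerate=True)
    tol = 1e-12 * max(1.0, abs(t_obs))
    if 2**n <= EXHAUSTIVE_LIMIT:
        codes = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((codes[:, None] >> np.arange(n)) & 1)
        t_null = signs @ d / n
        p = float(np.mean(np.abs(t_null) >= abs(t_obs) - tol))
        return RandomizationResult(t_obs, p, 2**n, True, seed)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = signs @ d / n
    count = int(np.sum(np.abs(t_null) >= abs(t_obs) - tol))
    p = (count + 1) / (n_perm + 1)
    return RandomizationResult(t_obs, float(p), n_perm, False, seed)
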