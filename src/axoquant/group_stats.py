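"""Group comparison statistics.

Scalar group comparisons are normality-gated: both groups pass a
Shapiro–Wilk test → unpaired two-sided Student t; otherwise a two-sided
Mann–Whitney U (exact when the smaller group has ≤ 8 observations and
there are no ties, normal approximation with mid-ranks and tie-corrected
variance otherwise).

Profile comparisons run one two-sided Mann–Whitney per position across the
per-image profile values of the two groups, then control the false
discovery rate jointly across positions at level ``q`` (default 5%) by a
step-up procedure — either the two-stage Benjamini–Krieger–Yekutieli
(``bky``, the default of the graphing software the field commonly uses) or
plain Benjamini–Hochberg (``bh``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ScalarTestResult", "ProfileComparison", "shapiro_wilk",
           "mann_whitney", "compare_scalars", "fdr_discoveries",
           "compare_profiles"]


@dataclass(frozen=True)
class ScalarTestResult:
    test_used: str            # 'student_t' | 'mann_whitney'
    statistic: float
    p_value: float
    normality_p: tuple[float, float]
    group_ns: tuple[int, int]


@dataclass(frozen=True)
class ProfileComparison:
    positions: np.ndarray     # µm, positions actually tested
    u_statistic: np.ndarray
    p_values: np.ndarray      # raw two-sided Mann–Whitney p per position
    discovery: np.ndarray     # bool, FDR-controlled at level q
    q: float
    method: str               # 'bky' | 'bh'
    excluded_positions: np.ndarray  # µm, dropped for insufficient data


def shapiro_wilk(sample) -> float:
    """Shapiro–Wilk normality p-value; requires 3 ≤ n ≤ 5000, non-constant."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality test")
    return float(stats.shapiro(x).pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: (U of the first sample, p).

    Exact null distribution when min(n) ≤ 8 and the pooled sample is
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_scalars(a, b, alpha_normality: float = 0.05) -> ScalarTestResult:
    """Normality-gated two-group scalar comparison (see module docstring)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs n >= 3")
    pa = shapiro_wilk(a) if np.ptp(a) > 0 else 0.0
    pb = shapiro_wilk(b) if np.ptp(b) > 0 else 0.0
    if pa > alpha_normality and pb > alpha_normality:
        res = stats.ttest_ind(a, b)
        return ScalarTestResult("student_t", float(res.statistic),
                                float(res.pvalue), (pa, pb),
                                (a.size, b.size))
    u, p = mann_whitney(a, b)
    return ScalarTestResult("mann_whitney", u, p, (pa, pb), (a.size, b.size))


def fdr_discoveries(p_values, q: float = 0.05, method: str = "bky") -> np.ndarray:
    """Step-up FDR control: boolean discovery vector at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if q <= 0:
        return np.zeros(p.size, dtype=bool)
    key = {"bh": "fdr_bh", "bky": "fdr_tsbky"}.get(method)
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}")
    reject, *_ = multipletests(p, alpha=q, method=key)
    return reject


def compare_profiles(group_a, group_b, q: float = 0.05,
                     method: str = "bky", min_n: int = 3) -> ProfileComparison:
    """Per-position Mann–Whitney between two groups of per-image profiles.

    ``group_a``/``group_b`` are :class:`~axoquant.profiles.Profile` objects
    (their ``per_image`` matrices are the observations) or plain
    ``(positions, per_image_matrix)`` pairs.  Positions present in both
    groups are tested; positions with fewer than ``min_n`` valid
    observations in either group are excluded and reported.
    """
    pos_a, mat_a = _as_matrix(group_a)
    pos_b, mat_b = _as_matrix(group_b)
    common, ia, ib = np.intersect1d(np.round(pos_a, 9), np.round(pos_b, 9),
                                    return_indices=True)
    mat_a, mat_b = mat_a[:, ia], mat_b[:, ib]

    n_a = np.sum(~np.isnan(mat_a), axis=0)
    n_b = np.sum(~np.isnan(mat_b), axis=0)
    testable = (n_a >= min_n) & (n_b >= min_n)
    excluded = common[~testable]
    positions = common[testable]

    u = np.empty(positions.size)
    p = np.empty(positions.size)
    for j, k in enumerate(np.flatnonzero(testable)):
        a = mat_a[:, k][~np.isnan(mat_a[:, k])]
        b = mat_b[:, k][~np.isnan(mat_b[:, k])]
        u[j], p[j] = mann_whitney(a, b)
    disc = fdr_discoveries(p, q=q, method=method)
    return ProfileComparison(positions, u, p, disc, float(q), method,
                             excluded)


def _as_matrix(group):
    if hasattr(group, "per_image"):
        return np.asarray(group.positions, float), np.asarray(group.per_image,
                                                              float)
    positions, mat = group
    return np.asarray(positions, float), np.atleast_2d(np.asarray(mat, float))
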