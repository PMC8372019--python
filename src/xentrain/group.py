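"""Linking behavioral and neural entrainment across subjects.

Subjects are partitioned into low/medium/high cross-modal behavioral
entrainment groups by 1-D k-means on their circular-linear correlations; a
linear-trend contrast then tests whether visual-electrode ITPC rises across
those groups, and a Spearman correlation probes the same relationship on a
continuous scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = ["kmeans_groups", "linear_trend_contrast", "rank_correlation"]

GROUP_ORDER = ("low", "medium", "high")


def kmeans_groups(
    behavioral_r: np.ndarray, k: int = 3, seed: int = 0, n_init: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """1-D k-means grouping of behavioral entrainment values.

    Returns ``(labels, centers)`` where labels are 'low'/'medium'/'high'
    ordered by ascending cluster center (for k = 3; otherwise 'g0', 'g1', ...
    by ascending center).  Deterministic given ``seed``.
    """
    x = np.asarray(behavioral_r, dtype=float).reshape(-1, 1)
    if len(x) < k:
        raise ValueError("need at least k subjects")
    if len(np.unique(x)) < k:
        raise ValueError("fewer distinct values than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_.ravel())
    names = list(GROUP_ORDER) if k == 3 else [f"g{i}" for i in range(k)]
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    labels = np.array([names[rank[lab]] for lab in km.labels_])
    centers = np.sort(km.cluster_centers_.ravel())
    return labels, centers


def linear_trend_contrast(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, tuple[int, int], float]:
    """Linear-trend contrast (-1, 0, +1) across low/medium/high group means.

    Uses the pooled within-group mean square as the error term:
    ``F = (sum w_i m_i)^2 / (MSW * sum w_i^2 / n_i)`` with df (1, N - 3).
    Returns ``(F, (1, N - 3), p)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    weights = {"low": -1.0, "medium": 0.0, "high": 1.0}
    groups = [values[labels == g] for g in GROUP_ORDER]
    if any(len(g) == 0 for g in groups):
        raise ValueError("all three groups must be non-empty")
    n = len(values)
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / (n - k)
    w = np.array([weights[g] for g in GROUP_ORDER])
    contrast = float(w @ means)
    se2 = msw * float((w**2 / ns).sum())
    f = contrast**2 / se2
    df = (1, n - k)
    p = float(stats.f.sf(f, *df))
    return float(f), df, p


def rank_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (tie-aware), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
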