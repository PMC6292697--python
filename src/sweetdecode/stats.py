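"""Shared statistical primitives: rank-based auROC, bootstrap CIs, permutation p-values.

The auROC here is the probability that a draw from ``x`` exceeds a draw from
``y``, with ties contributing one half — i.e. the Mann-Whitney U statistic
scaled to [0, 1].  All selectivity and preference analyses in the package are
built on this single implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "auroc",
    "auroc_bootstrap_ci",
    "permutation_pvalue",
    "auroc_permutation_test",
    "ranksum_pvalue",
    "pearson_r",
]


def auroc(x: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve separating samples ``x`` (positive) from ``y``.

    Equals P(X > Y) + 0.5 P(X = Y); 0.5 means the two distributions are
    indistinguishable, 1.0 that every x exceeds every y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("auroc requires at least one observation per group")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks handle ties
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def auroc_bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the auROC, resampling within each group."""
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix = rng.integers(0, x.size, size=(n_boot, x.size))
    iy = rng.integers(0, y.size, size=(n_boot, y.size))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = auroc(x[ix[b]], y[iy[b]])
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def permutation_pvalue(k_exceed: int, n_perm: int) -> float:
    """Corrected permutation p-value p = (k + 1) / (n + 1)."""
    return (k_exceed + 1) / (n_perm + 1)


def auroc_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided label-shuffle test of auROC against 0.5.

    Labels are permuted without replacement; ``k`` counts permutations whose
    |auROC - 0.5| is at least the observed one.  Returns (auroc, p).
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = auroc(x, y)
    pooled = np.concatenate([x, y])
    nx = x.size
    k = 0
    thr = abs(obs - 0.5) - 1e-12
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(auroc(perm[:nx], perm[nx:]) - 0.5) >= thr:
            k += 1
    return obs, permutation_pvalue(k, n_perm)


def ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small untied samples (combined n <= 20), otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ranksum requires non-empty groups")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient (nan if either input is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
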