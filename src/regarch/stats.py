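"""Permutation and rank statistics used by the comparative analyses.

Pearson correlation with a random-permutation p-value, the Mantel and
partial Mantel tests on distance matrices, the Wilcoxon rank-sum test,
and the (unscaled) median absolute deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import DistanceMatrix

__all__ = [
    "StatResult",
    "pearson_permutation",
    "mantel",
    "wilcoxon_rank_sum",
    "mad",
]

DEFAULT_N_PERM = 9999


@dataclass
class StatResult:
    name: str
    value: float
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    extra: dict | None = None


def _check_variance(v: np.ndarray, what: str) -> None:
    if np.ptp(v) == 0:
        raise ValueError(f"{what} has zero variance")


def pearson_permutation(x, y, n_perm: int = DEFAULT_N_PERM,
                        seed: int = 0) -> StatResult:
    """Pearson r with a two-tailed random-permutation p-value.

    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), permuting y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    _check_variance(x, "x")
    _check_variance(y, "y")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    xn = xc / np.sqrt((xc ** 2).sum())
    hits = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        r = float(xn @ yc / np.sqrt((yc ** 2).sum()))
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return StatResult(name="pearson_permutation", value=r_obs, p_value=p,
                      n_permutations=n_perm, seed=seed)


def _offdiag_upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel(X: DistanceMatrix, Y: DistanceMatrix,
           Z: DistanceMatrix | None = None,
           n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> StatResult:
    """Mantel test (Pearson on off-diagonal upper triangles).

    With Z, the partial statistic r_XY.Z = (r_XY - r_XZ r_YZ) /
    sqrt((1-r_XZ^2)(1-r_YZ^2)). The p-value permutes rows+columns of Y
    jointly, one-tailed on r >= r_obs (the vegan convention).
    """
    if X.labels != Y.labels or (Z is not None and Z.labels != X.labels):
        raise ValueError("distance matrices must share the same ordered labels")
    n = X.n
    if n < 4:
        raise ValueError("need at least 4 objects")

    x = _offdiag_upper(X.values)
    z = _offdiag_upper(Z.values) if Z is not None else None
    _check_variance(x, "X off-diagonal")
    if z is not None:
        _check_variance(z, "Z off-diagonal")

    def statistic(ym: np.ndarray) -> float:
        y = _offdiag_upper(ym)
        _check_variance(y, "Y off-diagonal")
        r_xy = np.corrcoef(x, y)[0, 1]
        if z is None:
            return float(r_xy)
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
        if denom == 0:
            raise ValueError("degenerate partial correlation (|r| = 1 with Z)")
        return float((r_xy - r_xz * r_yz) / denom)

    r_obs = statistic(Y.values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = Y.values[np.ix_(perm, perm)]
        if statistic(yp) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return StatResult(
        name="partial_mantel" if Z is not None else "mantel",
        value=r_obs, p_value=p, n_permutations=n_perm, seed=seed)


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided",
                      method: str = "auto") -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    With ``method='auto'``: exact enumeration when max(n_a, n_b) <= 10
    and there are no ties; otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (max(len(a), len(b)) <= 10 and no_ties) \
            else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method,
                           use_continuity=True)
    return StatResult(name="wilcoxon_rank_sum", value=float(res.statistic),
                      p_value=float(res.pvalue), extra={"method": method})


def mad(v) -> float:
    """Median absolute deviation, unscaled (no 1.4826 consistency factor)."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    return float(np.median(np.abs(v - np.median(v))))
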