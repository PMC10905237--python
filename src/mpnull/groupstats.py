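"""Stratified and clustered nonparametric comparisons.

Implements the comparison toolkit used on population tables: the
Cochran–Mantel–Haenszel common odds ratio with exact/Monte-Carlo permutation
inference over brood-size strata, a clustered Wilcoxon rank-sum test with
within-cluster permutation inference, Welch's t-test, and Krippendorff's
alpha (with a bootstrap confidence interval) for the consistency of repeated
population measurements within species.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .records import PopulationRecord, assign_brood_size_cluster

__all__ = [
    "StratifiedTable",
    "CMHResult",
    "ClusteredRankTestResult",
    "AlphaResult",
    "TTestResult",
    "build_stratified_table",
    "mantel_haenszel_cor",
    "stratum_lor",
    "cmh_permutation_test",
    "clustered_rank_sum_test",
    "welch_t",
    "krippendorff_alpha",
    "alpha_bootstrap_ci",
]


@dataclass(frozen=True)
class StratifiedTable:
    """2×2×S counts: strata[s] = [[a, b], [c, d]] with rows = groups A/B,
    columns = outcome yes/no."""

    strata: tuple

    def __post_init__(self):
        arr = np.asarray(self.strata, dtype=int)
        if arr.ndim != 3 or arr.shape[1:] != (2, 2):
            raise ValueError("strata must be an S×2×2 array of counts")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        return np.asarray(self.strata, dtype=int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CMHResult:
    cor: float
    clor: float
    stratum_lors: tuple
    p_value: float
    n_permutations: int | str
    seed: int | None = None


@dataclass(frozen=True)
class ClusteredRankTestResult:
    w: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    ci: tuple
    n_boot: int
    metric: str
    seed: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def build_stratified_table(
    records: Sequence[PopulationRecord],
    group_by: Callable[[PopulationRecord], object],
    outcome: Callable[[PopulationRecord], bool],
    cluster_of: Callable[[PopulationRecord], int] | None = None,
    groups: tuple | None = None,
    n_strata: int = 6,
) -> StratifiedTable:
    """Count records into a 2×2×S table of group × outcome × cluster.

    ``group_by`` must yield exactly two levels (pass ``groups`` to pin their
    order: first = row A); records whose group is None/unknown are excluded
    with a warning.  ``cluster_of`` defaults to the six-bin mean-brood-size
    clustering.
    """
    if cluster_of is None:
        cluster_of = lambda r: assign_brood_size_cluster(r.mean_brood_size)
    labels = []
    kept = []
    for r in records:
        g = group_by(r)
        if g is None:
            _warnings.warn(f"record {r.population_id!r} has undefined group; excluded")
            continue
        labels.append(g)
        kept.append(r)
    if groups is None:
        groups = tuple(sorted(set(labels), key=str))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 group levels, got {groups}")
    counts = np.zeros((n_strata, 2, 2), dtype=int)
    for g, r in zip(labels, kept):
        s = cluster_of(r) - 1
        row = groups.index(g)
        col = 0 if outcome(r) else 1
        counts[s, row, col] += 1
    return StratifiedTable(tuple(map(tuple, (tuple(map(tuple, s)) for s in counts))))


def mantel_haenszel_cor(t: StratifiedTable) -> float:
    """Mantel–Haenszel common odds ratio Σ aᵢdᵢ/nᵢ / Σ bᵢcᵢ/nᵢ.

    Strata with zero total are skipped; a zero denominator returns +inf with
    a warning.
    """
    c = t.counts.astype(float)
    n = c.sum(axis=(1, 2))
    keep = n > 0
    c, n = c[keep], n[keep]
    num = (c[:, 0, 0] * c[:, 1, 1] / n).sum()
    den = (c[:, 0, 1] * c[:, 1, 0] / n).sum()
    if den == 0:
        if num == 0:
            raise ValueError("all cross-products are zero; COR undefined")
        _warnings.warn("Mantel–Haenszel denominator is zero; returning +inf")
        return math.inf
    return float(num / den)


def stratum_lor(t: StratifiedTable, continuity: float = 0.5) -> list[float]:
    """Per-stratum log odds ratios log(ad/bc), with a continuity constant
    added to every cell of a stratum that contains a zero."""
    out = []
    for s in t.counts.astype(float):
        a, b, c, d = s[0, 0], s[0, 1], s[1, 0], s[1, 1]
        if s.sum() == 0:
            out.append(float("nan"))
            continue
        if min(a, b, c, d) == 0:
            a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
        out.append(float(math.log((a * d) / (b * c))))
    return out


def _clor(counts: np.ndarray) -> float:
    n = counts.sum(axis=(1, 2))
    keep = n > 0
    c, n = counts[keep].astype(float), n[keep]
    num = (c[:, 0, 0] * c[:, 1, 1] / n).sum()
    den = (c[:, 0, 1] * c[:, 1, 0] / n).sum()
    if num == 0 and den == 0:
        return 0.0
    if den == 0:
        return math.inf
    if num == 0:
        return -math.inf
    return math.log(num / den)


def cmh_permutation_test(
    t: StratifiedTable,
    mode: str = "monte_carlo",
    n_perm: int = 9999,
    seed: int = 0,
    exact_budget: int = 2_000_000,
) -> CMHResult:
    """Permutation test of the common log odds ratio.

    The null distribution permutes group labels independently within each
    stratum with both margins fixed, so the stratum 'a' cells are independent
    (central) hypergeometric draws.  ``exact`` mode enumerates the joint
    distribution when the state space fits ``exact_budget``, else falls back
    to Monte Carlo with a warning.  Two-sided p: probability of |CLOR| at
    least as extreme as observed (Monte-Carlo mode adds the +1/(N+1)
    finite-sample correction).
    """
    counts = t.counts
    row1 = counts.sum(axis=2)[:, 0]  # group-A margin per stratum
    col1 = counts.sum(axis=1)[:, 0]  # outcome-yes margin per stratum
    n = counts.sum(axis=(1, 2))
    if np.all((row1 == 0) | (row1 == n) | (col1 == 0) | (col1 == n)):
        _warnings.warn("degenerate table: a margin is zero in every stratum")
        return CMHResult(
            cor=1.0, clor=0.0, stratum_lors=tuple(stratum_lor(t)),
            p_value=1.0, n_permutations=0, seed=seed,
        )
    obs = abs(_clor(counts))
    lors = tuple(stratum_lor(t))
    try:
        cor = mantel_haenszel_cor(t)
    except ValueError:
        cor = 1.0
    clor = _clor(counts)

    # support of each stratum's a-cell under fixed margins
    los = np.maximum(0, row1 + col1 - n)
    his = np.minimum(row1, col1)
    sizes = his - los + 1
    if mode == "exact" and np.prod(sizes.astype(float)) > exact_budget:
        _warnings.warn("exact enumeration exceeds budget; falling back to Monte Carlo")
        mode = "monte_carlo"

    def clor_of_a(a_vec: np.ndarray) -> float:
        c = np.empty_like(counts)
        c[:, 0, 0] = a_vec
        c[:, 0, 1] = row1 - a_vec
        c[:, 1, 0] = col1 - a_vec
        c[:, 1, 1] = n - row1 - col1 + a_vec
        return _clor(c)

    if mode == "exact":
        supports = [np.arange(lo, hi + 1) for lo, hi in zip(los, his)]
        pmfs = [
            stats.hypergeom.pmf(sup, nn, cc, rr)
            for sup, nn, cc, rr in zip(supports, n, col1, row1)
        ]
        p = 0.0
        for combo in product(*(range(len(s)) for s in supports)):
            a_vec = np.array([supports[i][c] for i, c in enumerate(combo)])
            if abs(clor_of_a(a_vec)) >= obs - 1e-12:
                p += float(np.prod([pmfs[i][c] for i, c in enumerate(combo)]))
        return CMHResult(cor, clor, lors, min(p, 1.0), "exact", seed)

    rng = np.random.default_rng(seed)
    hits = 0
    a_draws = np.column_stack([
        rng.hypergeometric(col1[s], n[s] - col1[s], row1[s], size=n_perm)
        if n[s] > 0 and row1[s] > 0 else np.zeros(n_perm, dtype=int)
        for s in range(len(n))
    ])
    for i in range(n_perm):
        if abs(clor_of_a(a_draws[i])) >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return CMHResult(cor, clor, lors, p, n_perm, seed)


def _clustered_w(values: np.ndarray, is_a: np.ndarray, cluster: np.ndarray) -> float:
    """Standardised clustered rank-sum statistic for group A.

    Within each cluster, values are mid-ranked; group A's rank sum is centred
    at its within-cluster permutation expectation and the contributions are
    summed and scaled by the square root of the summed permutation variances.
    Clusters containing only one group contribute nothing.
    """
    num = 0.0
    var = 0.0
    for c in np.unique(cluster):
        m = cluster == c
        na = int(is_a[m].sum())
        nb = int((~is_a[m]).sum())
        if na == 0 or nb == 0:
            continue
        r = stats.rankdata(values[m])
        nn = na + nb
        num += r[is_a[m]].sum() - na * (nn + 1) / 2.0
        var += na * nb / (nn * (nn - 1.0)) * ((r - r.mean()) ** 2).sum()
    if var == 0:
        return 0.0
    return num / math.sqrt(var)


def clustered_rank_sum_test(
    values: Sequence[float],
    group: Sequence,
    cluster: Sequence,
    n_perm: int = 2000,
    seed: int = 0,
) -> ClusteredRankTestResult:
    """Clustered Wilcoxon rank-sum test with within-cluster permutations.

    Compares two groups on ``values`` while controlling for the clustered
    confounder; significance from ``n_perm`` random permutations of group
    labels within clusters (two-sided on |W|, with the +1 correction).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group)
    cl = np.asarray(cluster)
    if not (len(v) == len(g) == len(cl)):
        raise ValueError("values, group and cluster must have equal length")
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    is_a = g == levels[0]
    w_obs = _clustered_w(v, is_a, cl)
    if np.all(v == v[0]):
        return ClusteredRankTestResult(0.0, 1.0, n_perm, seed)
    rng = np.random.default_rng(seed)
    masks = [cl == c for c in np.unique(cl)]
    hits = 0
    perm = is_a.copy()
    for _ in range(n_perm):
        for m in masks:
            sub = perm[m]
            rng.shuffle(sub)
            perm[m] = sub
        if abs(_clustered_w(v, perm, cl)) >= abs(w_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ClusteredRankTestResult(float(w_obs), float(p), n_perm, seed)


def welch_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


def _alpha_from_units(units: list[np.ndarray], metric: str) -> float:
    pooled = np.concatenate(units)
    n = len(pooled)
    if metric == "interval":
        dist = lambda x, y: (x - y) ** 2
    elif metric == "ratio":
        dist = lambda x, y: ((x - y) / (x + y)) ** 2 if (x + y) != 0 else 0.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d_obs = 0.0
    for u in units:
        m = len(u)
        s = sum(dist(u[i], u[j]) for i in range(m) for j in range(m) if i != j)
        d_obs += s / (m - 1)
    d_obs /= n
    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_exp += dist(pooled[i], pooled[j])
    d_exp /= n * (n - 1)
    if d_exp == 0:
        return 1.0
    return 1.0 - d_obs / d_exp


def _pairable_units(matrix) -> list[np.ndarray]:
    units = []
    for row in np.asarray(matrix, dtype=float):
        vals = row[~np.isnan(row)]
        if len(vals) >= 2:
            units.append(vals)
    return units


def krippendorff_alpha(matrix, metric: str = "interval") -> float:
    """Krippendorff's alpha for a units × observers grid with missing cells.

    α = 1 − D_o/D_e: observed disagreement over the disagreement expected if
    the pooled pairable values were assigned at random.  Units with fewer
    than two non-missing values are unpairable and ignored (standard
    accounting); ``metric`` is squared difference (``interval``) or the
    normalised squared difference (``ratio``).
    """
    units = _pairable_units(matrix)
    if len(units) < 2:
        raise ValueError("need at least 2 units with at least 2 non-missing values")
    return float(_alpha_from_units(units, metric))


def alpha_bootstrap_ci(
    matrix, metric: str = "interval", n_boot: int = 1000, seed: int = 0
) -> AlphaResult:
    """Percentile bootstrap CI for alpha, resampling units with replacement."""
    units = _pairable_units(matrix)
    if len(units) < 2:
        raise ValueError("need at least 2 units with at least 2 non-missing values")
    point = float(_alpha_from_units(units, metric))
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(units), size=len(units))
        draws.append(_alpha_from_units([units[i] for i in idx], metric))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return AlphaResult(alpha=point, ci=(float(lo), float(hi)), n_boot=n_boot,
                       metric=metric, seed=seed)
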