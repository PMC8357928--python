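"""Compositional distances, clustering heuristics, PERMANOVA and metadata screens.

Between-sample distance is the Jensen-Shannon divergence (natural log, used
directly rather than its square root).  The number of community clusters
follows a merge-height rule on a hierarchical dendrogram: descending merge
heights are scanned until two subsequent heights differ by less than
twofold.  PERMANOVA is computed from the distance-based sums of squares
with a label-permutation p-value (exact enumeration when the number of
distinct label arrangements is small).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, linkage
from scipy.spatial.distance import squareform

from .data_model import AbundanceTable, SubjectMetadata
from .stats_core import TestResult, contingency_chi_square, kruskal_wallis

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "jensen_shannon_divergence",
    "jensen_shannon_matrix",
    "merge_heights",
    "cluster_count_by_height",
    "cut_clusters",
    "permanova",
    "equal_frequency_bins",
    "metadata_association",
]

MAX_EXACT_ARRANGEMENTS = 10_000


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")
        self.values = np.clip(self.values, 0.0, None)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_perm: float
    n_permutations: int
    method_note: str = ""


def jensen_shannon_divergence(p, q) -> float:
    """JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m = (p+q)/2, natural log.

    Inputs are renormalized to sum 1; 0*log(0) := 0.  Bounded in [0, ln 2].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("all-zero composition")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log(p / m), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log(q / m), 0.0).sum()
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def jensen_shannon_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise JSD between the samples of an abundance table."""
    V = table.values
    totals = V.sum(axis=1)
    if (totals <= 0).any():
        bad = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has all-zero composition")
    P = V / totals[:, None]
    n = len(P)
    # vectorized pairwise: sum over taxa of x log x terms
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0).sum(axis=1)
    D = np.zeros((n, n))
    for i in range(n):
        M = 0.5 * (P[i][None, :] + P[i + 1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            mlogm = np.where(M > 0, M * np.log(M), 0.0).sum(axis=1)
        d = 0.5 * plogp[i] + 0.5 * plogp[i + 1:] - mlogm
        D[i, i + 1:] = D[i + 1:, i] = np.clip(d, 0.0, np.log(2.0))
    return DistanceMatrix(list(table.sample_ids), D)


def merge_heights(dist: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Descending dendrogram merge heights (length n_samples - 1)."""
    Z = linkage(dist.condensed(), method=method) if method != "average" \
        else average(dist.condensed())
    return np.sort(Z[:, 2])[::-1]


def cluster_count_by_height(heights, n_samples: int, ratio: float = 2.0) -> int:
    """Cluster count from the sub-twofold-step rule on descending heights.

    k = j + 1 for the smallest j (1-based) with h_j / h_{j+1} < ratio;
    if no such step exists every sample is its own cluster.  Always >= 2.
    """
    h = np.asarray(heights, dtype=float)
    if (h <= 0).any():
        raise ValueError("merge heights must be positive")
    if np.any(np.diff(h) > 1e-12):
        raise ValueError("heights must be sorted descending")
    for j in range(len(h) - 1):
        if h[j] / h[j + 1] < ratio:
            return max(j + 2, 2)
    return max(n_samples, 2)


def cut_clusters(dist: DistanceMatrix, k: int, method: str = "average") -> np.ndarray:
    """Flat cluster labels from cutting the dendrogram into k groups."""
    from scipy.cluster.hierarchy import fcluster

    Z = average(dist.condensed()) if method == "average" \
        else linkage(dist.condensed(), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and integer labels."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_within <= 0:
        return math.inf, r2
    F = (ss_between / (a - 1)) / (ss_within / (n - a))
    return F, r2


def _n_arrangements(counts) -> float:
    total = sum(counts)
    out = math.factorial(total)
    for c in counts:
        out //= math.factorial(c)
    return out


def permanova(
    dist: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA from distance-based sums of squares.

    p-value by label permutation, counting the observed arrangement among
    the permutations; when the number of distinct label arrangements is at
    most ``MAX_EXACT_ARRANGEMENTS`` all of them are enumerated instead.
    """
    labels = np.asarray(labels)
    codes = pd.factorize(labels)[0]
    counts = np.bincount(codes)
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    d2 = dist.values ** 2
    F_obs, r2 = _permanova_stats(d2, codes)

    n_arr = _n_arrangements(counts)
    if n_arr <= MAX_EXACT_ARRANGEMENTS:
        from sympy.utilities.iterables import multiset_permutations

        ge = 0
        total = 0
        for perm in multiset_permutations(list(codes)):
            F_p, _ = _permanova_stats(d2, np.asarray(perm))
            ge += F_p >= F_obs - 1e-12
            total += 1
        return PermanovaResult(F_obs, r2, ge / total, total, "exact enumeration")
    rng = np.random.default_rng(seed)
    ge = 1  # observed arrangement counts
    for _ in range(n_perm):
        F_p, _ = _permanova_stats(d2, rng.permutation(codes))
        ge += F_p >= F_obs - 1e-12
    return PermanovaResult(F_obs, r2, ge / (n_perm + 1), n_perm, "monte-carlo permutation")


def equal_frequency_bins(values, n_bins: int = 3) -> np.ndarray:
    """Rank-based equal-frequency binning with stable tie resolution.

    Sorted positions are split into ``n_bins`` contiguous blocks whose
    sizes differ by at most one; ties keep their original order.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    bins = np.empty(len(values), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def metadata_association(
    group_labels,
    metadata: SubjectMetadata,
    variables: list[str] | None = None,
    ordinal: set | None = None,
) -> dict[str, TestResult]:
    """Screen metadata variables against a sample grouping.

    Categorical variables use the chi-square test on the grouping x level
    contingency table (Yates correction only for 2x2); variables marked
    ordinal (weekly-frequency counts and the like) use Kruskal-Wallis
    across groups.  Age is pre-binned into three equal-frequency bins and
    tested on the chi-square route.  Single-level variables are skipped.
    """
    ordinal = set(ordinal or ())
    frame = metadata.frame
    if variables is None:
        variables = [c for c in frame.columns]
    groups = np.asarray(group_labels)
    results: dict[str, TestResult] = {}
    for var in variables:
        col = frame[var]
        if var == "age":
            col = pd.Series(equal_frequency_bins(col.to_numpy(float), 3),
                            index=frame.index, name="age")
        if var in ordinal:
            parts = [col[groups == g].to_numpy(float) for g in np.unique(groups)]
            results[var] = kruskal_wallis(parts)
            continue
        if col.nunique() < 2:
            continue
        table = pd.crosstab(groups, col).to_numpy()
        results[var] = contingency_chi_square(table)
    return results
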