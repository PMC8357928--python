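"""Shared statistical primitives for the association pipeline.

Every hypothesis-test helper returns a :class:`TestResult` so downstream
stages handle one shape regardless of the underlying test.  Rank statistics
use average (mid-)ranks throughout, matching the R defaults of the tools the
pipeline emulates.  All model logarithms are natural logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "LinearFit",
    "wilcoxon_rank_sum",
    "spearman_correlation",
    "adjust_pvalues",
    "contingency_chi_square",
    "kruskal_wallis",
    "fit_linear_model",
]

# Combined sample size up to which the rank-sum test uses exact enumeration
# of the null distribution (ties force the normal approximation).
EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (U, rho, chi-square, H, ...).
    p_value : float
        Two- or one-sided p-value in [0, 1] depending on the test.
    direction : int
        Sign of the effect: -1, 0 or +1; 0 when undefined or null.
    method_note : str
        Short note on how the p-value was obtained (exact vs approximate).
    """

    statistic: float
    p_value: float
    direction: int = 0
    method_note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")


@dataclass
class LinearFit:
    """Ordinary least-squares fit with per-coefficient two-sided t-tests.

    Coefficient names key every per-coefficient map.  When the design is
    rank-deficient the affected coefficients carry NaN inference and
    ``rank_deficient`` is set.
    """

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    residual_variance: float
    n_obs: int
    df_resid: int
    rank_deficient: bool = False
    aliased: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, name: str) -> float:
        return self.coefficients[name]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of a location shift.

    Uses exact enumeration of the null permutation distribution when the
    combined sample size is at most ``EXACT_WILCOXON_MAX_N`` and there are
    no ties; otherwise the tie-corrected normal approximation with
    continuity correction.  ``direction`` is the sign of the rank-biserial
    correlation (equivalently of U1 - n1*n2/2).
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < n1 + n2
    exact = (n1 + n2) <= EXACT_WILCOXON_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    u1 = float(res.statistic)
    delta = u1 - n1 * n2 / 2.0
    direction = int(np.sign(delta))
    note = "exact enumeration" if exact else "normal approximation, tie-corrected, continuity"
    return TestResult(u1, float(res.pvalue), direction, note)


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation with a t-distribution p-value.

    rho is the Pearson correlation of mid-ranks.  A constant input leaves
    rho undefined: the result carries NaN statistic/p and a flag note.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, np.nan, 0, "undefined: constant input")
    rho, p = stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), int(np.sign(rho)), "t approximation")


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or Bonferroni."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]


def contingency_chi_square(table, continuity_correction: bool | None = None) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    Yates continuity correction defaults to on for 2x2 tables and is never
    applied to larger tables.  Zero row/column margins are rejected.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    is2x2 = table.shape == (2, 2)
    if continuity_correction is None:
        continuity_correction = is2x2
    res = stats.chi2_contingency(table, correction=continuity_correction and is2x2)
    note = "Yates continuity correction" if (continuity_correction and is2x2) else "Pearson"
    return TestResult(float(res.statistic), float(res.pvalue), 0, note)


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups.

    When every observation is identical the statistic is 0 and p = 1
    (scipy raises on zero tie-corrected variance; we define the limit).
    """
    arrays = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, 0, "degenerate: all values identical")
    h, p = stats.kruskal(*arrays)
    return TestResult(float(h), float(p), 0, "chi-square approximation, tie-corrected")


def fit_linear_model(design, response, names: list[str] | None = None) -> LinearFit:
    """OLS with named coefficients and two-sided t-tests.

    Parameters
    ----------
    design : (n, p) array or DataFrame
        Model matrix including any intercept column.
    response : (n,) array
    names : list of str, optional
        Column names; taken from the DataFrame when omitted.

    Rank-deficient designs are fitted by pivoted elimination: aliased
    columns (those not adding rank) get NaN coefficients and inference,
    and ``rank_deficient`` is set — mirroring how R's ``lm`` reports
    aliased terms.  With zero residual degrees of freedom coefficients
    are still returned but all inference is NaN.
    """
    if hasattr(design, "columns"):
        if names is None:
            names = [str(c) for c in design.columns]
        X = np.asarray(design, dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("design and response row counts differ")
    if len(names) != p:
        raise ValueError("names length must match design columns")

    # Pivoted rank detection: keep the maximal independent column prefix set.
    rank = np.linalg.matrix_rank(X)
    keep = list(range(p))
    aliased: list[int] = []
    if rank < p:
        keep = []
        for j in range(p):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                aliased.append(j)
    Xk = X[:, keep]
    beta_k, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta_k
    df_resid = n - len(keep)
    rss = float(resid @ resid)
    sigma2 = rss / df_resid if df_resid > 0 else np.nan

    coefs = dict.fromkeys(names, np.nan)
    ses = dict.fromkeys(names, np.nan)
    ts = dict.fromkeys(names, np.nan)
    ps = dict.fromkeys(names, np.nan)
    for j, b in zip(keep, beta_k):
        coefs[names[j]] = float(b)
    if df_resid > 0:
        xtx_inv = np.linalg.inv(Xk.T @ Xk)
        se_k = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2)
        for j, b, se in zip(keep, beta_k, se_k):
            name = names[j]
            ses[name] = float(se)
            if se > 0:
                t = float(b / se)
                ts[name] = t
                ps[name] = float(2.0 * stats.t.sf(abs(t), df_resid))
    return LinearFit(
        coefficients=coefs,
        std_errors=ses,
        t_values=ts,
        p_values=ps,
        residual_variance=sigma2,
        n_obs=n,
        df_resid=max(df_resid, 0),
        rank_deficient=rank < p,
        aliased=tuple(names[j] for j in aliased),
    )
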