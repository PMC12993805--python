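"""Group comparisons, ordination and regression screening over per-site
burning summaries.

Sites are stratified by region, ecosystem type, elevation group (lowland
< 500 m, upland 500–1500 m, highland > 1500 m a.s.l.) and human-footprint
class (wilderness < 1, intact 1–4, highly modified > 4 on the 0–50 index).
Burning status per site is the median PRS over the analysis window, cube-root
transformed toward normality. Climatic covariates are input columns; the
screening/regression chain is: correlation screen against the response,
collinearity pruning (|r| > 0.8), then OLS with backward elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_elevation_group",
    "assign_footprint_class",
    "kruskal_wallis",
    "one_way_anova",
    "pca_climate",
    "screen_and_regress",
    "RegressionReport",
]

LOWLAND, UPLAND, HIGHLAND = "lowland", "upland", "highland"
WILDERNESS, INTACT, HIGHLY_MODIFIED = "wilderness", "intact", "highly_modified"


def assign_elevation_group(elevation_m: float) -> str:
    """Lowland below 500 m, upland 500–1500 m (boundaries included), highland
    above 1500 m a.s.l."""
    if elevation_m < 0:
        raise ValueError("elevation must be >= 0")
    if elevation_m < 500.0:
        return LOWLAND
    if elevation_m <= 1500.0:
        return UPLAND
    return HIGHLAND


def assign_footprint_class(value: float) -> str:
    """Human-footprint classes: wilderness < 1, intact 1–4 (boundaries
    included), highly modified > 4. Valid range of the index is 0–50."""
    if not 0.0 <= value <= 50.0:
        raise ValueError(f"footprint value {value} outside [0, 50]")
    if value < 1.0:
        return WILDERNESS
    if value <= 4.0:
        return INTACT
    return HIGHLY_MODIFIED


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test from mid-ranks with tie correction.

    Returns (H, p) with p from the chi-square approximation on k−1 df.
    All-identical data gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = stats.rankdata(pooled)  # mid-ranks
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + len(a)]
        h += r.sum() ** 2 / len(a)
        start += len(a)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0.0:  # all values identical
        return 0.0, 1.0
    h /= tie
    p = float(stats.chi2.sf(h, len(arrays) - 1))
    return float(h), p


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within mean-square ratio).

    Zero within-group variance with unequal means returns F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def pca_climate(
    data: pd.DataFrame, variables: list[str]
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """PCA of sites in standardized climate space.

    Variables are standardized to zero mean / unit variance and the
    correlation matrix is eigendecomposed; components are ordered by
    eigenvalue and signed so the largest-magnitude loading of each component
    is positive. Constant variables are dropped with a warning.

    Returns (scores, loadings DataFrame [variables × components],
    variance_explained in % summing to 100).
    """
    import warnings

    if len(data) < 3:
        raise ValueError("PCA needs at least 3 sites")
    X = data[list(variables)].to_numpy(dtype=float)
    if np.isnan(X).all(axis=0).any():
        raise ValueError("a requested variable is all-NA")
    keep = []
    for j, name in enumerate(variables):
        if np.nanstd(X[:, j]) == 0.0:
            warnings.warn(f"dropping constant variable {name!r}", stacklevel=2)
        else:
            keep.append(j)
    names = [variables[j] for j in keep]
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    corr = (Z.T @ Z) / len(Z)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry positive per component
    for c in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[i, c] < 0:
            eigvec[:, c] *= -1
    scores = Z @ eigvec
    var_explained = 100.0 * eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec, index=names, columns=[f"PC{i + 1}" for i in range(len(names))]
    )
    return scores, loadings, var_explained


@dataclass
class RegressionReport:
    """Result of the screen → prune → backward-eliminate OLS chain."""

    period: str
    screened_in: list[str]
    dropped_collinear: list[str]
    selected: list[str]
    coefficients: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    r_squared: float = float("nan")
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "screened_in": self.screened_in,
            "dropped_collinear": self.dropped_collinear,
            "selected": self.selected,
            "coefficients": self.coefficients,
            "pvalues": self.pvalues,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def screen_and_regress(
    data: pd.DataFrame,
    response: str,
    candidates: list[str],
    r_threshold: float = 0.25,
    collinearity_threshold: float = 0.8,
    alpha: float = 0.05,
    period: str = "0-2000",
) -> RegressionReport:
    """Correlation-screened multiple linear regression with backward selection.

    Step 1: keep candidates with |Pearson r| > *r_threshold* against the
    response (0.25 default; 0.3 is the alternative screen used for variable
    pre-selection). Step 2: among kept pairs with mutual |r| >
    *collinearity_threshold*, drop the member less correlated with the
    response. Step 3: OLS with backward elimination, removing the largest-p
    term until every remaining term has p < *alpha*. An empty surviving set
    is reported, not an error.
    """
    import statsmodels.api as sm

    y = data[response].to_numpy(dtype=float)
    n = len(y)

    r_vs_response = {
        c: float(np.corrcoef(data[c].to_numpy(dtype=float), y)[0, 1]) for c in candidates
    }
    screened = [c for c in candidates if abs(r_vs_response[c]) > r_threshold]

    dropped: list[str] = []
    kept = list(screened)
    for i, a in enumerate(screened):
        for b in screened[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            r_ab = float(
                np.corrcoef(
                    data[a].to_numpy(dtype=float), data[b].to_numpy(dtype=float)
                )[0, 1]
            )
            if abs(r_ab) > collinearity_threshold:
                loser = a if abs(r_vs_response[a]) < abs(r_vs_response[b]) else b
                dropped.append(loser)
    kept = [c for c in kept if c not in dropped]

    report = RegressionReport(
        period=period, screened_in=screened, dropped_collinear=dropped, selected=[], n=n
    )
    current = list(kept)
    while current:
        X = sm.add_constant(data[current].to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        pvals = dict(zip(current, fit.pvalues[1:]))
        worst = max(pvals, key=pvals.get)
        if pvals[worst] >= alpha:
            current.remove(worst)
            continue
        report.selected = list(current)
        report.coefficients = {
            "intercept": float(fit.params[0]),
            **{c: float(v) for c, v in zip(current, fit.params[1:])},
        }
        report.pvalues = {c: float(v) for c, v in pvals.items()}
        report.r_squared = float(fit.rsquared)
        break
    return report
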