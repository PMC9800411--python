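"""Nonparametric statistics over regional MAD tables.

The study table is long-format: one row per (specimen, comparison, region)
with its MAD in mm.  The analysis layer mirrors the study design —
descriptives as median/IQR/range, Kruskal–Wallis across measurement areas
with Dunn's tie-corrected pairwise post hoc under Bonferroni adjustment for
unpaired region comparisons, Friedman's test for the within-specimen
(blocked) embedding-time comparison, and Spearman rank correlation for the
exploratory volume association.  All tests are two-sided at α = 0.05.

Conventions fixed here: quartiles use linear interpolation between order
statistics; Kruskal–Wallis and Friedman p-values use the χ² approximation
(k−1 df); Spearman p-values use the t approximation; Dunn's z statistics
use the published tie-corrected pooled-variance formula, which may differ
slightly from SPSS's variant on ties-heavy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Descriptives",
    "TestResult",
    "describe",
    "kruskal_wallis",
    "dunn_posthoc",
    "friedman",
    "spearman",
    "boxplot_stats",
    "make_study_table",
    "null_rejection_rate",
    "ALPHA",
]

ALPHA = 0.05

STUDY_TABLE_COLUMNS = ["specimen_id", "type", "comparison", "region", "mad_mm"]


class Descriptives(NamedTuple):
    median: float
    iqr: float
    min: float
    max: float


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with optional pairwise post hoc."""

    name: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    pairwise: Optional[pd.DataFrame] = None  # columns: group_1, group_2, z, p_raw, p_adj

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "df": None if self.df is None else float(self.df),
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def describe(values) -> Descriptives:
    """Median, interquartile range and range of a sample (linear-interpolation
    quartile convention)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("describe needs at least one value")
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return Descriptives(float(q2), float(q3 - q1), float(values.min()), float(values.max()))


def _check_groups(groups):
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    return groups


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis rank test across groups (tie-corrected H, χ² p-value
    with k−1 df).  All-identical data yields H = 0, p = 1."""
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    k = len(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal-wallis", 0.0, 1.0, df=k - 1)
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal-wallis", float(h), float(p), df=k - 1)


def dunn_posthoc(groups, labels=None, adjust: str = "bonferroni") -> TestResult:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − ΣT/(12(N−1)))·(1/n_i + 1/n_j)]
    with ΣT = Σ(t³ − t) over tied groups; two-sided normal p-values,
    Bonferroni-adjusted over all k(k−1)/2 pairs.
    """
    if adjust != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    groups = _check_groups(groups)
    k = len(groups)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match group count")

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = np.array([len(g) for g in groups])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)])

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var_factor = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    m = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se2 = var_factor * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_1": labels[i],
                "group_2": labels[j],
                "z": float(z),
                "p_raw": float(p),
                "p_adj": float(min(1.0, m * p)),
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["p_adj"].idxmin()]
    return TestResult(
        "dunn", statistic=float(best["z"]), p_value=float(best["p_adj"]), pairwise=table
    )


def friedman(blocked) -> TestResult:
    """Friedman's test on a complete blocked matrix (rows = specimens,
    columns = regions), with tie correction via within-row average ranks:

    χ² = (k−1)·Σ_j (R_j − n(k+1)/2)² / (Σ_ij r_ij² − n·k(k+1)²/4)

    All-tied rows give χ² = 0, p = 1.
    """
    x = np.asarray(blocked, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("friedman needs a 2-D matrix with >= 2 rows and >= 2 columns")
    if not np.isfinite(x).all():
        raise ValueError("friedman requires a complete matrix (no missing cells)")
    n, k = x.shape
    r = sps.rankdata(x, axis=1)
    col_sums = r.sum(axis=0)
    num = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    den = (r**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        return TestResult("friedman", 0.0, 1.0, df=k - 1)
    chi2 = num / den
    return TestResult("friedman", float(chi2), float(sps.chi2.sf(chi2, k - 1)), df=k - 1)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties; p-value from
    the t approximation with n−2 df."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("spearman needs at least 3 pairs")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), df=len(x) - 2)


def boxplot_stats(values) -> dict:
    """Box-plot summary following the study's figure convention: outliers
    are points further from the median than 1.5×IQR, extremes further than
    3×IQR; whiskers span the most extreme non-outlying points."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    dist = np.abs(values - q2)
    extreme = dist > 3 * iqr
    outlier = (dist > 1.5 * iqr) & ~extreme
    inliers = values[dist <= 1.5 * iqr]
    if len(inliers) == 0:
        inliers = np.array([q2])
    return {
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(v) for v in np.sort(values[outlier])],
        "extremes": [float(v) for v in np.sort(values[extreme])],
    }


def make_study_table(rows) -> pd.DataFrame:
    """Assemble and validate a long-format study table.

    ``rows`` yields (specimen_id, type, comparison, region, mad_mm).
    (specimen, comparison, region) must be unique and MAD nonnegative.
    """
    table = pd.DataFrame(rows, columns=STUDY_TABLE_COLUMNS)
    if (table["mad_mm"] < 0).any():
        raise ValueError("MAD values must be nonnegative")
    dup = table.duplicated(subset=["specimen_id", "comparison", "region"])
    if dup.any():
        raise ValueError(
            f"duplicate (specimen, comparison, region) rows: "
            f"{table.loc[dup, ['specimen_id', 'comparison', 'region']].values.tolist()}"
        )
    return table


def null_rejection_rate(
    test: str,
    n_sims: int = 10_000,
    n_groups: int = 3,
    n_per_group: int = 8,
    alpha: float = ALPHA,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of :func:`kruskal_wallis` or :func:`friedman`
    under the null (all observations from one continuous distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        if test == "kruskal-wallis":
            data = rng.standard_normal((n_groups, n_per_group))
            res = kruskal_wallis(list(data))
        elif test == "friedman":
            data = rng.standard_normal((n_per_group, n_groups))
            res = friedman(data)
        else:
            raise ValueError(f"unknown test {test!r}")
        rejections += res.p_value < alpha
    return rejections / n_sims
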