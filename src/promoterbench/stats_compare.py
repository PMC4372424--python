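"""Rank-based comparison of classifiers over multiple data sets.

The Demsar procedure: per data set, classifiers are ranked by performance
(rank 1 = best, ties averaged); the Friedman chi-square tests whether the
average ranks depart from the null of equal performance; when it rejects,
the Nemenyi post-hoc declares a pair significantly different when its
average-rank gap exceeds the critical difference
CD = q_alpha * sqrt(k(k+1)/(6N)).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata


@dataclass
class RankMatrix:
    datasets: list[str]
    classifiers: list[str]
    ranks: np.ndarray  # (N, k)

    @property
    def avg_ranks(self) -> np.ndarray:
        return self.ranks.mean(axis=0)

    @property
    def n_datasets(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_classifiers(self) -> int:
        return self.ranks.shape[1]


@dataclass
class ComparisonResult:
    friedman_statistic: float
    degrees_of_freedom: int
    p_value: float
    critical_difference: float
    significant_pairs: np.ndarray  # (k, k) bool, symmetric, false diagonal
    groups: list[list[str]]  # maximal non-significant groups, cover all
    avg_ranks: np.ndarray
    classifiers: list[str]


def average_ranks(
    scores: np.ndarray | pd.DataFrame,
    higher_is_better: bool = True,
    datasets: Optional[Sequence[str]] = None,
    classifiers: Optional[Sequence[str]] = None,
) -> RankMatrix:
    """Per-dataset ranks (1 = best), ties receiving the mean tied rank."""
    if isinstance(scores, pd.DataFrame):
        datasets = list(scores.index)
        classifiers = list(scores.columns)
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        ds = datasets[i] if datasets else f"row {i}"
        cl = classifiers[j] if classifiers else f"column {j}"
        raise ValueError(f"missing score for dataset {ds!r}, classifier {cl!r}")
    n, k = values.shape
    datasets = list(datasets) if datasets else [f"D{i + 1}" for i in range(n)]
    classifiers = (
        list(classifiers) if classifiers else [f"C{j + 1}" for j in range(k)]
    )
    signed = -values if higher_is_better else values
    ranks = np.vstack([rankdata(row) for row in signed])
    return RankMatrix(datasets=datasets, classifiers=classifiers, ranks=ranks)


def friedman_test(
    r: RankMatrix, alpha: float = 0.05
) -> tuple[float, int, float, bool]:
    """Friedman chi-square from average ranks.

    chi2_F = [12N / (k(k+1))] * [sum_j Rbar_j^2 - k(k+1)^2 / 4], df = k-1.
    Returns (statistic, df, p_value, reject).
    """
    n, k = r.n_datasets, r.n_classifiers
    if n < 2 or k < 2:
        raise ValueError("need at least 2 datasets and 2 classifiers")
    rbar = r.avg_ranks
    stat = 12.0 * n / (k * (k + 1)) * (np.sum(rbar**2) - k * (k + 1) ** 2 / 4.0)
    df = k - 1
    p = float(chi2.sf(stat, df))
    return float(stat), df, p, p < alpha


def iman_davenport(r: RankMatrix) -> tuple[float, tuple[int, int], float]:
    """The F-distributed correction of the Friedman statistic (optional)."""
    n, k = r.n_datasets, r.n_classifiers
    chi_f, _, _, _ = friedman_test(r)
    if n * (k - 1) == chi_f:
        raise ValueError("degenerate Iman-Davenport denominator")
    ff = (n - 1) * chi_f / (n * (k - 1) - chi_f)
    from scipy.stats import f as f_dist

    dof = (k - 1, (k - 1) * (n - 1))
    return float(ff), dof, float(f_dist.sf(ff, *dof))


def _load_q_table() -> pd.DataFrame:
    ref = resources.files("promoterbench").joinpath("data/nemenyi_q.tsv")
    return pd.read_csv(ref.open(), sep="\t", comment="#")


def nemenyi_q(k: int, alpha: float = 0.05) -> float:
    """Critical value q_alpha for k classifiers (bundled table, k = 2..20)."""
    table = _load_q_table()
    col = {0.05: "q_0.05", 0.10: "q_0.10"}.get(alpha)
    if col is None:
        raise ValueError("alpha must be 0.05 or 0.10")
    row = table[table["k"] == k]
    if row.empty:
        raise ValueError(f"k={k} outside the bundled q table range 2..20")
    return float(row[col].iloc[0])


def critical_difference(k: int, n: int, alpha: float = 0.05) -> float:
    return nemenyi_q(k, alpha) * np.sqrt(k * (k + 1) / (6.0 * n))


def nemenyi(
    r: RankMatrix, alpha: float = 0.05, warn_not_rejected: bool = True
) -> ComparisonResult:
    """Nemenyi post-hoc: pairwise significance and maximal connected groups.

    A pair differs significantly when |Rbar_i - Rbar_j| > CD.  Groups are
    the maximal sets of classifiers (consecutive in average-rank order) with
    no internal significant pair — the "connected" bars of a CD diagram.
    """
    stat, df, p, rejected = friedman_test(r, alpha)
    if not rejected and warn_not_rejected:
        import warnings

        warnings.warn(
            "Friedman test did not reject; Nemenyi post-hoc is advisory only",
            stacklevel=2,
        )
    k, n = r.n_classifiers, r.n_datasets
    cd = critical_difference(k, n, alpha)
    rbar = r.avg_ranks
    diff = np.abs(rbar[:, None] - rbar[None, :])
    significant = diff > cd
    np.fill_diagonal(significant, False)

    order = np.argsort(rbar, kind="stable")
    groups: list[list[str]] = []
    for start in range(k):
        end = start
        while end + 1 < k and rbar[order[end + 1]] - rbar[order[start]] <= cd:
            end += 1
        members = [r.classifiers[order[t]] for t in range(start, end + 1)]
        if not any(set(members) <= set(g) for g in groups):
            groups.append(members)
    return ComparisonResult(
        friedman_statistic=stat,
        degrees_of_freedom=df,
        p_value=p,
        critical_difference=cd,
        significant_pairs=significant,
        groups=groups,
        avg_ranks=rbar,
        classifiers=list(r.classifiers),
    )


def cd_diagram_text(result: ComparisonResult) -> str:
    """Plain-text critical-difference diagram: classifiers sorted by average
    rank with bars joining groups that are not significantly different."""
    order = np.argsort(result.avg_ranks, kind="stable")
    lines = [
        f"CD = {result.critical_difference:.3f} "
        f"(Friedman chi2 = {result.friedman_statistic:.2f}, "
        f"p = {result.p_value:.2e})"
    ]
    for t in order:
        lines.append(f"  {result.avg_ranks[t]:5.2f}  {result.classifiers[t]}")
    for g, members in enumerate(result.groups, start=1):
        if len(members) > 1:
            lines.append(f"  group {g}: {' ~ '.join(members)}")
    return "\n".join(lines)
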