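"""Orchestration of the routine statistics around the pipeline outputs.

Variables are z-scored (sample standard deviation) before multivariate
analysis; treatment differences are screened with Shapiro-Wilk, tested
with Kruskal-Wallis and resolved pairwise with Dunn's rank-based post hoc
test (Holm-adjusted by default), summarized as compact letter displays at
alpha = 0.05.  PCA is run on the z-scored table.  All test internals are
delegated to scipy / scikit-learn; Dunn's z statistics are assembled here
from scipy primitives because no installed package exposes them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_normalize",
    "dunn_test",
    "compact_letters",
    "group_tests",
    "pca_scores",
    "GroupTestResult",
]


def zscore_normalize(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Standardize columns to mean 0 and sample sd 1 (n-1 denominator).

    Non-numeric columns are passed through untouched.  A constant column
    cannot be standardized and raises with the column named.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    for col in columns:
        x = table[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column {col!r} is constant (or too short); cannot z-score")
        out[col] = (x - x.mean()) / sd
    return out


def dunn_test(
    groups: dict[str, np.ndarray], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's post hoc test on ranks of the pooled sample.

    For groups i, j the statistic is

        z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) )

    with mean ranks Rbar, pooled size N and tie correction
    T = sum(t^3 - t) / (12 (N - 1)).  Two-sided p-values are adjusted
    across the pairs with the given method ('holm', 'bonferroni', ...,
    or 'none').
    """
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    n = {g: len(groups[g]) for g in labels}
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    i0 = 0
    for g in labels:
        mean_rank[g] = ranks[i0 : i0 + n[g]].mean()
        i0 += n[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))

    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / n[g1] + 1.0 / n[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if adjust and adjust != "none":
        df["p_adj"] = multipletests(df["p_raw"], method=adjust)[1]
    else:
        df["p_adj"] = df["p_raw"]
    return df


def compact_letters(
    labels: list[str], pairwise_p: dict[tuple[str, str], float], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Insert-and-absorb algorithm over the significance relation; labels are
    processed in the given order and letters assigned alphabetically.
    """
    def sig(a: str, b: str) -> bool:
        p = pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))
        return p <= alpha

    letter_sets: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if not sig(a, b):
            continue
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets = [s for s in letter_sets if s]
    letter_sets.sort(key=lambda s: min(labels.index(x) for x in s))
    out = {g: "" for g in labels}
    for i, s in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in labels:
            if g in s:
                out[g] += ch
    return out


@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    statistic: float
    p_value: float
    shapiro_p: dict
    letters: dict
    skipped: bool = False
    reason: str = ""


def group_tests(
    table: pd.DataFrame,
    value_columns: list[str],
    group_column: str,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> list[GroupTestResult]:
    """Kruskal-Wallis + Dunn post hoc per variable, with letter groupings.

    Shapiro-Wilk normality p-values per group are recorded (screening
    only; the omnibus test is non-parametric regardless).  Variables with
    fewer than two groups of two observations are skipped with a warning.
    """
    results = []
    for col in value_columns:
        sub = table[[group_column, col]].dropna()
        groups = {
            str(g): grp[col].to_numpy(dtype=float)
            for g, grp in sub.groupby(group_column, sort=True)
        }
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            logger.warning("skipping %r: fewer than 2 usable groups", col)
            results.append(
                GroupTestResult(col, np.nan, np.nan, {}, {}, skipped=True,
                                reason="fewer than 2 groups with >= 2 observations")
            )
            continue
        shapiro = {}
        for g, v in usable.items():
            if len(v) >= 3 and np.ptp(v) > 0:
                shapiro[g] = float(stats.shapiro(v).pvalue)
        pooled = np.concatenate(list(usable.values()))
        if np.ptp(pooled) == 0.0:
            # identical values everywhere: no evidence of any difference
            letters = {g: "a" for g in usable}
            results.append(GroupTestResult(col, 0.0, 1.0, shapiro, letters))
            continue
        stat, p = stats.kruskal(*usable.values())
        dunn = dunn_test(usable, adjust=adjust)
        pairwise = {
            (r.group1, r.group2): r.p_adj for r in dunn.itertuples(index=False)
        }
        if p > alpha:
            # omnibus not significant: all groups share one letter
            letters = {g: "a" for g in usable}
        else:
            letters = compact_letters(list(usable), pairwise, alpha=alpha)
        results.append(GroupTestResult(col, float(stat), float(p), shapiro, letters))
    return results


def pca_scores(
    table: pd.DataFrame, columns: list[str], n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA on the z-scored columns: (scores, loadings, explained variance ratio).

    Standardizing first makes this identical to a correlation-matrix PCA.
    """
    z = zscore_normalize(table[columns], columns)
    n_components = n_components or min(len(columns), len(table) - 1)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z.to_numpy(dtype=float))
    pc_names = [f"PC{i+1}" for i in range(pca.n_components_)]
    scores_df = pd.DataFrame(scores, index=table.index, columns=pc_names)
    loadings_df = pd.DataFrame(pca.components_.T, index=columns, columns=pc_names)
    return scores_df, loadings_df, pca.explained_variance_ratio_
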