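"""Population summaries and nonparametric condition comparisons.

Co-localization metrics across nuclei are not normally distributed, so
conditions (e.g. untreated vs TSA-treated populations) are compared with the
Mann-Whitney U test pairwise and the Kruskal-Wallis test as the omnibus.
Tests are two-sided throughout and p-values are reported raw (no
multiple-testing correction by default).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionComparison",
    "summarize",
    "mann_whitney",
    "kruskal_wallis",
    "compare_conditions",
]

#: Largest per-group size for which the exact Mann-Whitney null distribution
#: is enumerated (all C(n+m, n) group assignments of the pooled values).
EXACT_LIMIT = 8


@dataclasses.dataclass
class ConditionComparison:
    """All pairwise and omnibus tests for one metric."""

    metric: str
    conditions: list[str]
    pairwise_p: pd.DataFrame  # symmetric, NaN diagonal
    pairwise_u: pd.DataFrame
    kruskal_h: float
    kruskal_p: float
    n: dict[str, int]


def summarize(results: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Mean, sample SD and n per metric column (Table-style summary row)."""
    if len(results) == 0:
        raise ValueError("no results to summarize")
    if metrics is None:
        metrics = [
            c
            for c in results.columns
            if results[c].dtype.kind in "fiu" and c not in ("id",)
        ]
    rows = []
    for m in metrics:
        v = results[m].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        rows.append(
            dict(
                metric=m,
                mean=float(np.mean(v)) if v.size else math.nan,
                sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                n=int(v.size),
            )
        )
    return pd.DataFrame(rows)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x-vs-y via midranks (ties share rank mass)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(
    x, y, exact_limit: int = EXACT_LIMIT
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For samples no larger than ``exact_limit`` the exact two-sided p-value is
    computed by enumerating every assignment of the pooled values to the two
    groups (correct under ties); larger samples use the tie-corrected normal
    approximation with continuity correction.  Returns ``(U, p)`` with U for
    x-versus-y.  Pooled samples that are all identical give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    u_obs = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0

    if max(len(x), len(y)) <= exact_limit:
        n = len(x)
        idx = np.arange(len(pooled))
        lo = hi = total = 0
        for comb in itertools.combinations(idx, n):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u <= u_obs + 1e-12:
                lo += 1
            if u >= u_obs - 1e-12:
                hi += 1
        p = min(1.0, 2.0 * min(lo / total, hi / total))
        return u_obs, p

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    if math.isnan(p):  # zero tie-corrected variance
        p = 1.0
    return u_obs, p


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with its chi-square p-value.

    Degenerate input (all pooled values identical) gives ``(0, 1)``.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def compare_conditions(
    tables: dict[str, pd.DataFrame],
    metrics: list[str],
    exact_limit: int = EXACT_LIMIT,
) -> list[ConditionComparison]:
    """Pairwise Mann-Whitney matrix plus Kruskal-Wallis omnibus per metric.

    ``tables`` maps a condition label to its per-nucleus result table.
    """
    if len(tables) < 2:
        raise ValueError("at least 2 conditions required")
    conditions = list(tables)
    out = []
    for metric in metrics:
        samples = {
            c: tables[c][metric].dropna().to_numpy(dtype=float) for c in conditions
        }
        p_mat = pd.DataFrame(np.nan, index=conditions, columns=conditions)
        u_mat = pd.DataFrame(np.nan, index=conditions, columns=conditions)
        for a, b in itertools.combinations(conditions, 2):
            u, p = mann_whitney(samples[a], samples[b], exact_limit=exact_limit)
            p_mat.loc[a, b] = p_mat.loc[b, a] = p
            u_mat.loc[a, b] = u_mat.loc[b, a] = u
        h, p_kw = kruskal_wallis([samples[c] for c in conditions])
        out.append(
            ConditionComparison(
                metric=metric,
                conditions=conditions,
                pairwise_p=p_mat,
                pairwise_u=u_mat,
                kruskal_h=h,
                kruskal_p=p_kw,
                n={c: int(len(samples[c])) for c in conditions},
            )
        )
    return out


def comparison_frame(comparisons: list[ConditionComparison]) -> pd.DataFrame:
    """Flatten comparisons into a long-form table for CSV export."""
    rows = []
    for comp in comparisons:
        for a, b in itertools.combinations(comp.conditions, 2):
            rows.append(
                dict(
                    metric=comp.metric,
                    test="mann_whitney",
                    group_a=a,
                    group_b=b,
                    statistic=comp.pairwise_u.loc[a, b],
                    p_value=comp.pairwise_p.loc[a, b],
                    n_a=comp.n[a],
                    n_b=comp.n[b],
                )
            )
        rows.append(
            dict(
                metric=comp.metric,
                test="kruskal_wallis",
                group_a="|".join(comp.conditions),
                group_b="",
                statistic=comp.kruskal_h,
                p_value=comp.kruskal_p,
                n_a=sum(comp.n.values()),
                n_b=0,
            )
        )
    return pd.DataFrame(rows)
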