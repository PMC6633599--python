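"""Thin group-comparison wrappers (two-tailed t-test, Kruskal-Wallis with a
Dunn / Bonferroni follow-up) used for category and condition comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

TESTS = ("t_test_two_tailed", "kruskal_wallis")


@dataclass
class GroupComparison:
    test: str
    labels: list
    sizes: list
    statistic: float
    pvalue: float
    posthoc: Optional[pd.DataFrame] = None
    degenerate: bool = False


def _dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis, with tie
    correction and Bonferroni adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for k in labels:
        n = len(groups[k])
        mean_ranks[k] = float(np.mean(ranks[start:start + n]))
        sizes[k] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group1": a, "group2": b, "z": z, "p_raw": p,
                     "p_bonferroni": min(1.0, p * m) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows)


def compare_groups(groups: Mapping[str, Sequence[float]], test: str) -> GroupComparison:
    """Compare samples across labelled groups.

    test='t_test_two_tailed' requires exactly two groups (each n >= 2);
    test='kruskal_wallis' accepts >= 2 and, with more than two, attaches a
    Dunn pairwise follow-up with Bonferroni correction.  All-identical
    values make Kruskal-Wallis undefined; that case is flagged degenerate
    with a NaN p-value.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    g = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    labels = list(g)
    sizes = [len(g[k]) for k in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if test == "t_test_two_tailed":
        if len(labels) != 2:
            raise ValueError("t-test compares exactly 2 groups")
        if any(s < 2 for s in sizes):
            raise ValueError("t-test requires n >= 2 per group")
        res = sps.ttest_ind(g[labels[0]], g[labels[1]])
        return GroupComparison(test=test, labels=labels, sizes=sizes,
                               statistic=float(res.statistic), pvalue=float(res.pvalue))
    pooled = np.concatenate(list(g.values()))
    if np.all(pooled == pooled[0]):
        return GroupComparison(test=test, labels=labels, sizes=sizes,
                               statistic=float("nan"), pvalue=float("nan"),
                               degenerate=True)
    stat, p = sps.kruskal(*[g[k] for k in labels])
    posthoc = _dunn_posthoc(g) if len(labels) > 2 else None
    return GroupComparison(test=test, labels=labels, sizes=sizes,
                           statistic=float(stat), pvalue=float(p), posthoc=posthoc)
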