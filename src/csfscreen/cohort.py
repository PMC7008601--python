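"""Demographic group comparisons: chi-square, Kruskal-Wallis, Dunn post-hoc.

Categorical variables (sex) are compared with Pearson's chi-square without
continuity correction; continuous/ordinal variables (age, MMSE, FRSSD) with
the Kruskal-Wallis rank test (tie-corrected) followed by Dunn's pairwise
z-tests on mean ranks.  Missing values are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.stats as ss

__all__ = ["GroupComparison", "chi_square_counts", "kruskal_wallis", "dunn_pairwise"]


@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] | None = None

    def to_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.pairwise is not None:
            d["pairwise"] = {" vs ".join(k): v for k, v in self.pairwise.items()}
        return d


def chi_square_counts(counts, variable: str = "") -> GroupComparison:
    """Pearson chi-square on a group x category contingency table.

    No continuity correction; p from the chi-square distribution with
    (r-1)(c-1) degrees of freedom.  Rows or columns summing to zero are a
    hard error (expected counts would vanish).
    """
    table = np.asarray(counts, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = ss.chi2_contingency(table, correction=False)
    return GroupComparison(
        variable=variable,
        test="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def _group_arrays(values: dict[str, list[float]]) -> dict[str, np.ndarray]:
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    empty = [g for g, a in arrays.items() if a.size == 0]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    return arrays


def kruskal_wallis(values: dict[str, list[float]], variable: str = "") -> GroupComparison:
    """Kruskal-Wallis H test across groups with midrank tie correction.

    All observations identical is reported as the degenerate H = 0, p = 1.
    """
    arrays = _group_arrays(values)
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        return GroupComparison(variable, "kruskal_wallis", 0.0, 1.0)
    h, p = ss.kruskal(*arrays.values())
    return GroupComparison(variable, "kruskal_wallis", float(h), float(min(max(p, 0.0), 1.0)))


def dunn_pairwise(
    values: dict[str, list[float]], adjust: str = "none", variable: str = ""
) -> GroupComparison:
    """Dunn's pairwise mean-rank z-tests after Kruskal-Wallis.

    For groups i, j with mean ranks Ri, Rj over the pooled midranks of N
    observations, z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj)) where
    T = sum(t^3 - t) / (12 (N - 1)) corrects for ties.  Two-sided normal
    p-values, optionally Bonferroni or Sidak adjusted over the pairs; with
    two groups and no adjustment this reduces to the plain z-test on the
    mean-rank difference.
    """
    if adjust not in ("none", "bonferroni", "sidak"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    arrays = _group_arrays(values)
    labels = list(arrays)
    pooled = np.concatenate([arrays[g] for g in labels])
    n_total = pooled.size
    ranks = ss.rankdata(pooled)  # midranks

    mean_ranks: dict[str, float] = {}
    start = 0
    for g in labels:
        n = arrays[g].size
        mean_ranks[g] = float(ranks[start : start + n].mean())
        start += n

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(labels, 2))
    n_pairs = len(pairs)
    pairwise: dict[tuple[str, str], float] = {}
    z_max = 0.0
    for gi, gj in pairs:
        ni, nj = arrays[gi].size, arrays[gj].size
        se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
        p = 2.0 * ss.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        elif adjust == "sidak":
            p = 1.0 - (1.0 - min(p, 1.0)) ** n_pairs
        pairwise[(gi, gj)] = float(min(max(p, 0.0), 1.0))
        z_max = max(z_max, abs(z))

    return GroupComparison(
        variable=variable,
        test="dunn_pairwise",
        statistic=float(z_max),
        p_value=float(min(pairwise.values())) if pairwise else 1.0,
        pairwise=pairwise,
    )
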