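"""Normality-routed group comparisons.

Comparisons follow the published scheme: every group's sample is checked
with a Shapiro–Wilk test; if all groups look normal at the chosen alpha the
family is compared by one-way ANOVA with Bonferroni-adjusted pairwise
t-tests, otherwise by Kruskal–Wallis one-way ANOVA on ranks with Dunn's
post hoc test (Bonferroni-adjusted z-comparisons of mean ranks, with tie
correction).  All tests are two-tailed at alpha = 0.05 by default.

Routing is per comparison family: if *any* group fails normality the whole
family takes the rank-based route.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = ["compare_groups", "compare_two_groups", "dunn_test", "ComparisonResult"]


@dataclass
class ComparisonResult:
    route: str  # anova_bonferroni | kruskal_dunn | ttest | ranksum | degenerate
    omnibus_stat: float
    omnibus_p: float
    normality_p: dict[str, float]
    pairwise: pd.DataFrame  # columns: group1, group2, stat, p_raw, p_adj
    group_stats: pd.DataFrame  # index: group; columns: n, mean, median, sem
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise.p_adj < self.alpha]
        return list(zip(sig.group1, sig.group2))


def _clean_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ConfigurationError("need at least two groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 3:
            raise ConfigurationError(f"group {name!r} has n < 3 after removing missing values")
        out[name] = arr
    return out


def _group_stats(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, arr in groups.items():
        rows.append(
            {
                "group": name,
                "n": arr.size,
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "sem": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _shapiro_p(arr: np.ndarray) -> float:
    """Shapiro-Wilk p-value; constant samples are treated as non-normal."""
    if np.ptp(arr) == 0:
        return 0.0
    return float(sps.shapiro(arr).pvalue)


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post hoc test on pooled ranks, Bonferroni-adjusted.

    For groups i, j the statistic is the difference of mean ranks over its
    standard error ``sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))`` with
    tie term ``T = sum(t^3 - t)`` over tied values; p-values are two-sided
    normal tail probabilities times the number of comparisons (clipped at 1).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = float(ranks[start : start + n].mean())
        sizes[g] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_core * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"group1": g1, "group2": g2, "stat": z, "p_raw": p_raw,
             "p_adj": min(1.0, len(pairs) * p_raw)}
        )
    return pd.DataFrame(rows)


def _bonferroni_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        res = sps.ttest_ind(groups[g1], groups[g2], equal_var=True)
        rows.append(
            {"group1": g1, "group2": g2, "stat": float(res.statistic),
             "p_raw": float(res.pvalue), "p_adj": min(1.0, len(pairs) * float(res.pvalue))}
        )
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> ComparisonResult:
    """Route a family of >= 2 groups through the normality-based scheme.

    All groups pass Shapiro–Wilk at ``alpha`` -> one-way ANOVA with
    Bonferroni pairwise t-tests; any failure -> Kruskal–Wallis with Dunn's
    post hoc.  Two-group families route to a t-test or rank-sum test
    directly.  Groups need n >= 3 each (missing values dropped first).
    """
    clean = _clean_groups(groups)
    gstats = _group_stats(clean)

    pooled = np.concatenate(list(clean.values()))
    if np.ptp(pooled) == 0:  # all observations identical: nothing to detect
        names = list(clean)
        pairs = list(itertools.combinations(names, 2))
        pairwise = pd.DataFrame(
            [{"group1": a, "group2": b, "stat": 0.0, "p_raw": 1.0, "p_adj": 1.0}
             for a, b in pairs]
        )
        return ComparisonResult(
            route="degenerate", omnibus_stat=0.0, omnibus_p=1.0,
            normality_p={g: float("nan") for g in names},
            pairwise=pairwise, group_stats=gstats, alpha=alpha,
        )

    normality = {g: _shapiro_p(arr) for g, arr in clean.items()}
    normal = all(p > alpha for p in normality.values())

    if len(clean) == 2:
        return compare_two_groups(clean, alpha=alpha, _normality=normality)

    if normal:
        stat, p = sps.f_oneway(*clean.values())
        pairwise = _bonferroni_pairwise(clean)
        route = "anova_bonferroni"
    else:
        stat, p = sps.kruskal(*clean.values())
        pairwise = dunn_test(clean)
        route = "kruskal_dunn"
    return ComparisonResult(
        route=route, omnibus_stat=float(stat), omnibus_p=float(p),
        normality_p=normality, pairwise=pairwise, group_stats=gstats, alpha=alpha,
    )


def compare_two_groups(
    groups: dict[str, np.ndarray], alpha: float = 0.05, _normality=None
) -> ComparisonResult:
    """Two-group comparison: t-test when both samples look normal,
    Wilcoxon rank-sum (Mann-Whitney) otherwise."""
    clean = _clean_groups(groups)
    if len(clean) != 2:
        raise ConfigurationError("compare_two_groups needs exactly two groups")
    normality = _normality or {g: _shapiro_p(arr) for g, arr in clean.items()}
    (g1, a), (g2, b) = clean.items()
    if all(p > alpha for p in normality.values()):
        res = sps.ttest_ind(a, b, equal_var=True)
        route = "ttest"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        route = "ranksum"
    pairwise = pd.DataFrame(
        [{"group1": g1, "group2": g2, "stat": float(res.statistic),
          "p_raw": float(res.pvalue), "p_adj": float(res.pvalue)}]
    )
    return ComparisonResult(
        route=route, omnibus_stat=float(res.statistic), omnibus_p=float(res.pvalue),
        normality_p=normality, pairwise=pairwise, group_stats=_group_stats(clean),
        alpha=alpha,
    )
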