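"""Nonparametric comparisons across strategies and observers.

Strategy comparisons use the Kruskal-Wallis test applied pairwise (a
two-group KW is the tie-corrected rank-sum test), with Benjamini-Hochberg
step-up correction at a false discovery rate of 10% within each metric
family; observer comparisons use the Wilcoxon signed-rank test on values
paired by lesion.  All tests delegate to scipy.stats / statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "kruskal_wallis",
    "benjamini_hochberg",
    "wilcoxon_signed_rank",
    "compare_strategies",
    "compare_observers",
    "global_kruskal",
    "tally_choices",
    "select_best_tally",
    "summarize_metrics",
]

DEFAULT_FDR_Q = 0.10


@dataclass
class ComparisonResult:
    """One hypothesis in a BH-corrected family of rank tests."""

    metric: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    fdr_q: float = DEFAULT_FDR_Q
    significant: bool = False
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    All values are ranked jointly with midranks; a fully degenerate input
    (every pooled value identical) returns H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def benjamini_hochberg(pvalues, q: float = DEFAULT_FDR_Q) -> list[bool]:
    """BH step-up rejection decisions at FDR level ``q``."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    arr = np.asarray(pvalues, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(arr, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


def wilcoxon_signed_rank(paired_a, paired_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null distribution is used for n <= 25, otherwise the normal
    approximation with continuity correction.  Returns (W, p) where W is
    the signed-rank statistic reported by the backend.  A fully degenerate
    input (all differences zero) returns (0, 1).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    if nz.size < 5:
        raise ValueError("need >= 5 non-zero differences")
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", correction=(method == "approx"),
                       alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _strategy_order(table: pd.DataFrame) -> list[str]:
    preferred = ["select_best", "gradient", "threshold", "manual"]
    present = set(table["strategy"].unique())
    ordered = [s for s in preferred if s in present]
    ordered += sorted(present - set(ordered))
    return ordered


def compare_strategies(
    table: pd.DataFrame,
    metric: str,
    q: float = DEFAULT_FDR_Q,
    kind: str = "pairwise",
) -> list[ComparisonResult]:
    """All pairwise two-group Kruskal-Wallis tests among strategies.

    Values for ``metric`` (restricted to rows of the given ``kind``) are
    grouped by strategy; the C(k, 2) pairwise tests form one BH family at
    FDR ``q``.
    """
    sub = table[(table["metric"] == metric) & (table["kind"] == kind)]
    strategies = _strategy_order(sub)
    if len(strategies) < 2:
        raise ValueError(f"need >= 2 strategies with metric {metric!r}")
    values = {s: sub.loc[sub["strategy"] == s, "value"].to_numpy() for s in strategies}
    results = []
    for a, b in combinations(strategies, 2):
        h, p = kruskal_wallis([values[a], values[b]])
        results.append(
            ComparisonResult(
                metric=metric, group_a=a, group_b=b, test="kruskal-wallis",
                statistic=h, p_value=p, fdr_q=q, n_a=len(values[a]), n_b=len(values[b]),
            )
        )
    for res, rej in zip(results, benjamini_hochberg([r.p_value for r in results], q)):
        res.significant = rej
    return results


def global_kruskal(table: pd.DataFrame, metric: str, kind: str = "pairwise") -> tuple[float, float]:
    """Context statistic: the k-group Kruskal-Wallis across all strategies."""
    sub = table[(table["metric"] == metric) & (table["kind"] == kind)]
    groups = [g["value"].to_numpy() for _, g in sub.groupby("strategy")]
    return kruskal_wallis(groups)


def compare_observers(
    table: pd.DataFrame,
    metric: str,
    strategy: str,
    q: float = DEFAULT_FDR_Q,
) -> list[ComparisonResult]:
    """Pairwise Wilcoxon signed-rank tests between observers, paired by lesion.

    Uses vs-MV rows of one strategy; observer pairs with too few non-zero
    paired differences are skipped.
    """
    sub = table[(table["metric"] == metric) & (table["kind"] == "vs_mv")
                & (table["strategy"] == strategy)]
    wide = sub.pivot(index="lesion", columns="obs_a", values="value")
    observers = sorted(wide.columns)
    results = []
    for a, b in combinations(observers, 2):
        pair = wide[[a, b]].dropna()
        try:
            w, p = wilcoxon_signed_rank(pair[a].to_numpy(), pair[b].to_numpy())
        except ValueError:
            continue
        results.append(
            ComparisonResult(
                metric=metric, group_a=a, group_b=b, test="wilcoxon-signed-rank",
                statistic=w, p_value=p, fdr_q=q, n_a=len(pair), n_b=len(pair),
            )
        )
    for res, rej in zip(results, benjamini_hochberg([r.p_value for r in results], q)):
        res.significant = rej
    return results


def tally_choices(labels, order=None) -> pd.DataFrame:
    """Preference counts and 1-d.p. percentages for a sequence of chosen labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("no choices to tally")
    if order is None:
        order = sorted(set(labels), key=labels.index)
    counts = {lb: labels.count(lb) for lb in order}
    total = len(labels)
    return pd.DataFrame(
        {
            "algorithm": list(order),
            "count": [counts.get(lb, 0) for lb in order],
            "pct": [round(100.0 * counts.get(lb, 0) / total, 1) for lb in order],
        }
    )


def select_best_tally(records) -> pd.DataFrame:
    """How often each predefined algorithm was chosen in select-the-best."""
    from .observers import Strategy
    from .segment import PANEL_LABELS

    labels = [r.provenance["chosen"] for r in records if r.strategy is Strategy.SELECT_BEST]
    if not labels:
        raise ValueError("no select-the-best records")
    return tally_choices(labels, order=list(PANEL_LABELS))


def summarize_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Quartile summaries (q1, median, q3, IQR) per strategy × kind × metric."""
    rows = []
    for (strategy, kind, metric), g in table.groupby(["strategy", "kind", "metric"]):
        v = g["value"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append((strategy, kind, metric, len(v), q1, med, q3, q3 - q1))
    return pd.DataFrame(
        rows, columns=["strategy", "kind", "metric", "n", "q1", "median", "q3", "iqr"]
    )
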