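"""Outcome-group statistics and report tables.

Non-parametric throughout: two-sided Mann-Whitney U tests contrast the
favorable and unfavorable surgery-outcome groups (patients without surgery
are described but never tested), Chi-squared tests compare event-type
proportions, and Bonferroni correction accounts for testing each accuracy
quantifier over six predictive->target pairings (0.01/6 -> 0.0017 for
significance, 0.05/6 -> 0.0083 for trends).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.01
ALPHA_TREND = 0.05
N_PAIRING_TESTS = 6

EXACT_MAX_N = 20  # full enumeration up to this combined sample size


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U test p-value.

    For combined sample sizes up to 20 the p-value is exact: the U
    statistic (computed from midranks, so ties are handled) is enumerated
    over all C(n1+n2, n1) group assignments and the two-sided p is the
    probability of a U at least as far from its null mean n1*n2/2 as
    observed. Larger samples use the normal approximation with tie and
    continuity correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    if n1 + n2 <= EXACT_MAX_N:
        # midranks doubled are integers -> exact integer arithmetic on 2U
        r2 = np.rint(2 * stats.rankdata(np.concatenate([a, b]))).astype(np.int64)
        u2_obs = int(r2[:n1].sum()) - n1 * (n1 + 1)  # 2*U1
        mean2 = n1 * n2  # 2 * n1*n2/2
        dev_obs = abs(u2_obs - mean2)
        r2_list = r2.tolist()
        offset = n1 * (n1 + 1)
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            u2 = sum(r2_list[i] for i in idx) - offset
            if abs(u2 - mean2) >= dev_obs:
                hits += 1
        return hits / comb(n1 + n2, n1)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def chi_squared(contingency) -> float:
    """Pearson chi-square p-value for a 2 x k count table (df = k − 1)."""
    table = np.asarray(contingency)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if np.any(table < 0) or not np.allclose(table, np.rint(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every margin must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)


@dataclass
class BonferroniAlpha:
    """Corrected significance level, exact and rounded to 4 decimals."""

    exact: float
    rounded: float


def bonferroni(alpha: float, m: int) -> BonferroniAlpha:
    """Bonferroni-corrected level alpha/m for a family of m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    exact = alpha / m
    return BonferroniAlpha(exact=exact, rounded=round(exact, 4))


def quartiles(values) -> tuple[float, float, float]:
    """(q1, median, q3) with linear interpolation (type-7)."""
    q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q1), float(med), float(q3)


@dataclass
class GroupComparison:
    """Median [q1, q3] per outcome group plus the favorable-vs-unfavorable MWU p."""

    pairing: str
    quantifier: str
    groups: dict  # outcome -> (q1, median, q3) or None if the group is empty
    p_value: float | None
    test: str = "MWU"
    significant: bool | None = None
    trend: bool | None = None


def outcome_contrast(
    results: pd.DataFrame,
    n_tests: int = N_PAIRING_TESTS,
    quantifiers: tuple[str, ...] = ("precision", "recall", "f1"),
) -> list[GroupComparison]:
    """Per pairing x quantifier: group summaries and the MWU contrast.

    ``results`` is epoch-level, with columns pairing, event_type,
    available, outcome and the quantifiers; event pairings enter through
    their type-aggregated ("all") rows. The no-surgery group is summarized
    but excluded from the test. Significance is flagged at the
    Bonferroni-corrected 0.01/n_tests and trends at 0.05/n_tests.
    """
    alpha_sig = bonferroni(ALPHA, n_tests).exact
    alpha_trend = bonferroni(ALPHA_TREND, n_tests).exact
    mask = results["available"] & results["event_type"].isin(["", "all"])
    data = results[mask]
    out = []
    for pairing in data["pairing"].unique():
        sub = data[data["pairing"] == pairing]
        for q in quantifiers:
            groups = {}
            for g in ("favorable", "unfavorable", "none"):
                vals = sub.loc[sub["outcome"] == g, q].to_numpy()
                groups[g] = quartiles(vals) if vals.size else None
            fav = sub.loc[sub["outcome"] == "favorable", q].to_numpy()
            unf = sub.loc[sub["outcome"] == "unfavorable", q].to_numpy()
            p = mann_whitney(fav, unf) if fav.size and unf.size else None
            out.append(
                GroupComparison(
                    pairing=pairing,
                    quantifier=q,
                    groups=groups,
                    p_value=p,
                    significant=None if p is None else p < alpha_sig,
                    trend=None if p is None else p < alpha_trend,
                )
            )
    return out


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparisons into a median [q1, q3] report table."""
    rows = []
    for c in comparisons:
        row: dict = {"pairing": c.pairing, "quantifier": c.quantifier}
        for g, summ in c.groups.items():
            if summ is None:
                row[f"{g}_median"] = row[f"{g}_q1"] = row[f"{g}_q3"] = float("nan")
            else:
                row[f"{g}_q1"], row[f"{g}_median"], row[f"{g}_q3"] = summ
        row["p_fav_vs_unfav"] = float("nan") if c.p_value is None else c.p_value
        row["significant"] = c.significant
        row["trend"] = c.trend
        rows.append(row)
    return pd.DataFrame(rows)


def format_comparison_table(comparisons: list[GroupComparison]) -> str:
    """Human-readable text table: one row per pairing x quantifier."""
    lines = [
        f"{'pairing':<14} {'quant':<10} {'favorable':<20} {'unfavorable':<20} "
        f"{'no surgery':<20} {'p (fav vs unf)':<14}"
    ]

    def fmt(summ):
        if summ is None:
            return "-"
        q1, med, q3 = summ
        return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"

    for c in comparisons:
        p = "-" if c.p_value is None else f"{c.p_value:.4g}"
        mark = "**" if c.significant else ("*" if c.trend else "")
        lines.append(
            f"{c.pairing:<14} {c.quantifier:<10} {fmt(c.groups.get('favorable')):<20} "
            f"{fmt(c.groups.get('unfavorable')):<20} {fmt(c.groups.get('none')):<20} "
            f"{p:<14}{mark}"
        )
    return "\n".join(lines)


def event_type_proportion_test(counts_a, counts_b) -> float:
    """Chi-squared p for differing event-type proportions between two groups.

    ``counts_a``/``counts_b`` are per-type event counts in the same type
    order, forming the 2 x k contingency table.
    """
    return chi_squared(np.vstack([counts_a, counts_b]))
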