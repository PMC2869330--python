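"""Enrichment statistics, family tabulations and the transposition rate.

The 2x2 test is a two-sided exact (Fisher-type) test computed by full
hypergeometric enumeration with exact integer combinatorics: every table
with the observed margins whose point probability does not exceed the
observed table's contributes to p.  A chi-square variant is provided for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import pandas as pd
from scipy import stats as sp_stats


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float
    group_labels: tuple[str, str] = ("group1", "group2")
    method: str = "exact"


@dataclass
class RateEstimate:
    n_events: int
    divergence_my: float
    years_per_event: float
    rounded_years_per_event: int


def exact_test_2x2(table, group_labels=("group1", "group2")) -> ContingencyResult:
    """Two-sided exact test on a 2x2 table of non-negative counts.

    p is the sum of hypergeometric point probabilities, over all tables
    with the observed margins, that are at most the observed table's point
    probability.  The comparison is made on exact integer products
    C(r1,k)*C(r2,c1-k) (the common denominator C(n,c1) cancels), so ties
    are resolved exactly rather than to floating-point tolerance.  The odds
    ratio is (a*d)/(b*c), with a 0.5 continuity correction applied to every
    cell when any cell is zero.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin in 2x2 table")
    n = r1 + r2
    obs_weight = comb(r1, a) * comb(r2, c1 - a)
    num = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs_weight:
            num += w
    p = num / comb(n, c1)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), orr, min(1.0, p), group_labels)


def chi2_test_2x2(table, group_labels=("group1", "group2")) -> ContingencyResult:
    """Chi-square alternative (sensitivity analysis), via scipy."""
    (a, b), (c, d) = table
    res = sp_stats.chi2_contingency([[a, b], [c, d]], correction=False)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), orr, float(res.pvalue), group_labels,
                             method="chi2")


def percent(count: int, total: int) -> float:
    """Percentage at one decimal place, the tables' formatting convention."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 1)


def transposition_rate(n_events: int, divergence_my: float) -> RateEstimate:
    """Years per transposition event: divergence (MY) * 1e6 / n_events,

    rounded to two significant figures for reporting.
    """
    if n_events <= 0 or divergence_my <= 0:
        raise ValueError("need positive event count and divergence")
    years = divergence_my * 1e6 / n_events
    from math import floor, log10
    digits = floor(log10(abs(years)))
    rounded = int(round(years, -int(digits) + 1))
    return RateEstimate(n_events, divergence_my, years, rounded)


def family_table(families: list[str], min_members: int = 2) -> pd.DataFrame:
    """Counts and percentages per family label.

    Families with fewer than ``min_members`` members are aggregated into an
    ``Other`` row; empty labels count as ``unknown``.  Percentages are of
    the whole gene set.
    """
    labels = [f if f else "unknown" for f in families]
    total = len(labels)
    counts = pd.Series(labels).value_counts()
    rows = []
    other = 0
    for fam, cnt in counts.items():
        if cnt >= min_members and fam != "other":
            rows.append({"family": fam, "count": int(cnt), "percent": percent(cnt, total)})
        else:
            other += int(cnt)
    if other:
        rows.append({"family": "Other", "count": other, "percent": percent(other, total)})
    df = pd.DataFrame(rows, columns=["family", "count", "percent"])
    return df.sort_values(["count", "family"], ascending=[False, True],
                          ignore_index=True)


def enrichment_tables(transposed: pd.DataFrame, control: pd.DataFrame) -> dict:
    """Repeat/parent enrichment contrasts between gene sets.

    Each input frame has one row per gene with boolean columns
    ``repeat_gt15``, ``repeat_gt30`` and ``has_parent``.  Returns the
    per-set summary (counts and percentages) and an exact-test result for
    each transposed-vs-control contrast.
    """
    if transposed.empty or control.empty:
        raise ValueError("empty gene set")
    summary_rows = []
    tests = {}
    for name, df in (("transposed", transposed), ("not_transposed", control)):
        n = len(df)
        summary_rows.append({
            "set": name,
            "n": n,
            "n_repeat_gt15": int(df["repeat_gt15"].sum()),
            "pct_repeat_gt15": percent(int(df["repeat_gt15"].sum()), n),
            "n_repeat_gt30": int(df["repeat_gt30"].sum()),
            "pct_repeat_gt30": percent(int(df["repeat_gt30"].sum()), n),
            "n_parent": int(df["has_parent"].sum()),
            "pct_parent": percent(int(df["has_parent"].sum()), n),
        })
    for col in ("repeat_gt15", "repeat_gt30", "has_parent"):
        a = int(transposed[col].sum())
        b = len(transposed) - a
        c = int(control[col].sum())
        d = len(control) - c
        try:
            tests[col] = exact_test_2x2(((a, b), (c, d)),
                                        group_labels=("transposed", "not_transposed"))
        except ValueError:
            tests[col] = None
    return {"summary": pd.DataFrame(summary_rows), "tests": tests}
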