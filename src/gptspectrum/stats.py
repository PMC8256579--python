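"""Exact and multiple-comparison statistics for between-group tests.

Fisher's exact test on 2x2 tables is computed by exact rational
hypergeometric summation (no floating-point tie tolerance, no normal
approximation): the one-sided p-value is the hypergeometric tail in the
direction of the observed association, and the two-sided p-value is the
point-probability definition — the sum of all tables (with the observed
margins) whose probability does not exceed that of the observed table.

Tukey's studentized-range test compares per-animal frequencies across all
treatment-group pairs, with the Tukey-Kramer margin for unbalanced groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from scipy.stats import studentized_range


@dataclass(frozen=True)
class Fisher2x2Result:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    p_one_sided: float
    odds_ratio: float


def _hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(top-left cell = a) for fixed margins, as an exact rational."""
    n = r1 + r2
    return Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), math.comb(n, c1))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> Fisher2x2Result:
    """Fisher's exact test on a 2x2 table of non-negative counts.

    Returns both sidedness conventions. For an all-zero table both
    p-values are 1 (no information).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in table {table!r}")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return Fisher2x2Result(
            table=((a, b), (c, d)), p_two_sided=1.0, p_one_sided=1.0,
            odds_ratio=float("nan"),
        )
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    pmf = {x: _hypergeom_pmf(x, r1, r2, c1) for x in range(lo, hi + 1)}
    observed = pmf[a]
    lower = sum(pmf[x] for x in range(lo, a + 1))
    upper = sum(pmf[x] for x in range(a, hi + 1))
    one_sided = min(lower, upper)
    two_sided = sum(p for p in pmf.values() if p <= observed)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return Fisher2x2Result(
        table=((a, b), (c, d)),
        p_two_sided=float(min(two_sided, Fraction(1))),
        p_one_sided=float(min(one_sided, Fraction(1))),
        odds_ratio=odds,
    )


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q_statistic: float
    p_adjusted: float
    significant_at_05: bool
    significant_at_01: bool


@dataclass(frozen=True)
class TukeyResult:
    comparisons: tuple[PairComparison, ...]
    pooled_within_variance: float
    df_error: int


def tukey_hsd(values_by_group: Mapping[str, Sequence[float]]) -> TukeyResult:
    """Tukey(-Kramer) all-pairs comparison of per-group values.

    Uses the classical one-way-ANOVA pooled within-group variance and the
    studentized-range distribution; unbalanced groups get the Tukey-Kramer
    standard error. Each group needs at least two values.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(values_by_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than two values")
    k = len(groups)
    ns = {g: len(values_by_group[g]) for g in groups}
    means = {g: sum(values_by_group[g]) / ns[g] for g in groups}
    n_total = sum(ns.values())
    df_error = n_total - k
    sse = sum(
        (v - means[g]) ** 2 for g in groups for v in values_by_group[g]
    )
    s2 = sse / df_error
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            ga, gb = groups[i], groups[j]
            diff = means[ga] - means[gb]
            se = math.sqrt(s2 / 2.0 * (1.0 / ns[ga] + 1.0 / ns[gb]))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
            else:
                q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_error)) if math.isfinite(q) else 0.0
            p = min(max(p, 0.0), 1.0)
            comparisons.append(
                PairComparison(
                    group_a=ga,
                    group_b=gb,
                    mean_diff=diff,
                    q_statistic=q,
                    p_adjusted=p,
                    significant_at_05=p < 0.05,
                    significant_at_01=p < 0.01,
                )
            )
    return TukeyResult(
        comparisons=tuple(comparisons),
        pooled_within_variance=s2,
        df_error=df_error,
    )
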