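"""Descriptive summary tables and two-group comparison tests.

Summaries mirror the print conventions of pharmacovigilance cohort
tables: counts with percents rounded half-up to two decimals against the
stated denominator, and continuous blocks reporting n, missing, mean,
sample SD, median, quartiles (linear interpolation between order
statistics), min and max.

Comparison contracts: categorical tables use Pearson's chi-square
(continuity correction off by default, Yates available) unless an
expected cell is below five, in which case the 2x2 Fisher exact test is
used; continuous variables use the two-sided Mann-Whitney U test, with
exact label-permutation enumeration at small sample sizes and the
tie-corrected normal approximation otherwise. Significance is two-sided
at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .records import EventRecord

__all__ = [
    "round_half_up", "ContinuousSummary", "SummaryTable", "TestResult",
    "summarize_categorical", "soc_distribution", "summarize_continuous",
    "compare_categorical", "compare_continuous",
]

ALPHA = 0.05


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table style."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ContinuousSummary:
    """The continuous block of a cohort table."""

    n: int
    missing: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None


@dataclass
class SummaryTable:
    """A categorical summary with optional continuous blocks attached."""

    table: pd.DataFrame
    continuous_blocks: dict = field(default_factory=dict)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # chi2 | chi2_yates | fisher | mann_whitney

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _resolve(case, variable):
    value = variable(case) if callable(variable) else getattr(case, variable)
    return value


def summarize_categorical(cohorts: dict, variable,
                          levels: Optional[Sequence] = None,
                          denominators: Optional[dict] = None) -> SummaryTable:
    """Per-level counts and percents for each group.

    ``variable`` is an attribute name or a callable on a case. ``levels``
    fixes row order and forces zero-count rows to appear; otherwise levels
    are taken from the data in first-appearance order. The percent
    denominator is each group's report total unless ``denominators``
    overrides it (e.g. with event totals).
    """
    if not cohorts:
        raise ValidationError("at least one group is required")
    counts = {}
    for group, cases in cohorts.items():
        c: dict = {}
        for case in cases:
            c[_resolve(case, variable)] = c.get(_resolve(case, variable), 0) + 1
        counts[group] = c
    if levels is None:
        levels = list(dict.fromkeys(
            lvl for c in counts.values() for lvl in c))
    data = {}
    for group, cases in cohorts.items():
        denom = (denominators or {}).get(group, len(cases))
        n = [counts[group].get(lvl, 0) for lvl in levels]
        pct = [round_half_up(100.0 * k / denom) if denom else float("nan")
               for k in n]
        data[(group, "count")] = n
        data[(group, "percent")] = pct
    df = pd.DataFrame(data, index=pd.Index(levels, name="level"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["group", "stat"])
    return SummaryTable(table=df)


def soc_distribution(events: Iterable[EventRecord]) -> pd.DataFrame:
    """Event counts and percents per system organ class.

    Sorted by descending count, ties broken alphabetically by SOC. Counts
    sum exactly to the number of event records.
    """
    events = list(events)
    counts: dict = {}
    for ev in events:
        counts[ev.soc] = counts.get(ev.soc, 0) + 1
    total = len(events)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "soc": [r[0] for r in rows],
            "count": [r[1] for r in rows],
            "percent": [round_half_up(100.0 * r[1] / total) for r in rows],
        }
    )


def summarize_continuous(values: Iterable[Optional[float]]) -> ContinuousSummary:
    """n, missing, mean, sample SD, median, Q1/Q3, min, max.

    Quartiles use linear interpolation between order statistics. With no
    non-missing values the statistics are all missing.
    """
    values = list(values)
    x = np.asarray([v for v in values if v is not None and not (
        isinstance(v, float) and math.isnan(v))], dtype=float)
    missing = len(values) - x.size
    if x.size == 0:
        return ContinuousSummary(n=0, missing=missing)
    return ContinuousSummary(
        n=int(x.size),
        missing=missing,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else None,
        median=float(np.median(x)),
        q1=float(np.quantile(x, 0.25)),
        q3=float(np.quantile(x, 0.75)),
        min=float(np.min(x)),
        max=float(np.max(x)),
    )


def expected_counts(table: np.ndarray) -> np.ndarray:
    """Expected cell counts under row/column independence."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    return rows * cols / table.sum()


def compare_categorical(table, yates: bool = False) -> TestResult:
    """Chi-square or Fisher exact test on an r x c count table.

    Fisher's exact test is applied when any expected cell count is below
    five; it is defined only for 2x2 tables here — larger sparse tables
    must be collapsed by the caller. The Fisher two-sided p sums the
    probabilities of all tables no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("degenerate table: a margin is zero")

    if np.any(expected_counts(t) < 5):
        if t.shape != (2, 2):
            raise ValidationError(
                "expected counts below 5 in a table larger than 2x2; "
                "collapse sparse levels and retry"
            )
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return TestResult(statistic=float(odds), p_value=float(p),
                          method="fisher")
    stat, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method="chi2_yates" if yates else "chi2")


_EXACT_ENUM_LIMIT = 200_000


def _mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Exact two-sided Mann-Whitney p by label-permutation enumeration.

    Uses midranks so ties are handled, and defines the two-sided p as the
    probability of a U at least as far from its null mean n1*n2/2 as the
    observed one — the enumeration distribution is symmetric under group
    relabelling, so this reduces to the classical tail doubling when there
    are no ties.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    dist = abs(u_obs - mu)
    total = 0
    hits = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - offset)
        total += 1
        if abs(u - mu) >= dist - 1e-9:
            hits += 1
    return TestResult(statistic=u_obs, p_value=hits / total,
                      method="mann_whitney")


def compare_continuous(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test, dropping missing values first.

    Exact enumeration is used when the smaller sample has at most eight
    observations (and the enumeration is tractable); otherwise the normal
    approximation with tie correction.
    """
    xa = np.asarray([v for v in x if v is not None], dtype=float)
    ya = np.asarray([v for v in y if v is not None], dtype=float)
    xa, ya = xa[~np.isnan(xa)], ya[~np.isnan(ya)]
    if xa.size == 0 or ya.size == 0:
        raise ValidationError("both samples need at least one value")
    small = min(xa.size, ya.size)
    if small <= 8 and math.comb(xa.size + ya.size, xa.size) <= _EXACT_ENUM_LIMIT:
        return _mannwhitney_exact(xa, ya)
    u, p = stats.mannwhitneyu(xa, ya, alternative="two-sided",
                              method="asymptotic")
    return TestResult(statistic=float(u), p_value=float(p),
                      method="mann_whitney")
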