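"""PT-level disproportionality screens, subgroups and heatmap matrices.

A screen compares one drug cohort against a background of all other
cleaned reports (``full_database`` comparator, the dominant convention)
or against reports sharing the indication (``within_indication``).
Counting is report-level: a report contributes at most one count per
preferred term no matter how often the term repeats.

Subgroup screens restrict *both* cohort and background to the stratum so
that demographic reporting imbalances do not masquerade as drug signals.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .cohort import assign_age_band
from .dispro import (ContingencyTable, GPSPrior, SignalThresholds,
                     compute_metrics, mgps_fit_prior)
from .errors import UnmappedTermError, ValidationError
from .records import MeddraDict, ReportCase

log = logging.getLogger(__name__)

__all__ = [
    "ScreenRow", "ScreenResult", "SubgroupSpec",
    "build_contingency", "run_screen", "rank_top",
    "subgroup_screen", "heatmap_matrix", "screen_to_frame",
]

SCREEN_COLUMNS = [
    "pt", "soc", "a", "b", "c", "d", "ror", "ror_lo95", "ror_hi95",
    "prr", "prr_chi2", "ic", "ic025", "ic975", "ebgm", "eb05",
    "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "flag_any",
    "flag_all_four",
]


@dataclass
class ScreenRow:
    pt: str
    soc: str
    table: ContingencyTable
    metrics: object


@dataclass
class ScreenResult:
    rows: list
    background_size: int
    cohort_size: int
    thresholds: SignalThresholds
    comparator_mode: str = "full_database"
    prior: Optional[GPSPrior] = None
    skipped: bool = False
    skip_reason: str = ""

    def __len__(self):
        return len(self.rows)


@dataclass(frozen=True)
class SubgroupSpec:
    """A stratification axis whose levels partition the cohort."""

    axis: str  # gender | age_band | seriousness

    def level_of(self, case: ReportCase) -> str:
        if self.axis == "gender":
            return case.sex if case.sex in ("F", "M") else "not_specified"
        if self.axis == "age_band":
            return assign_age_band(case.age_years)
        if self.axis == "seriousness":
            return "serious" if case.serious else "non_serious"
        raise ValidationError(f"unknown subgroup axis {self.axis!r}")

    @property
    def levels(self) -> tuple:
        return {
            "gender": ("F", "M", "not_specified"),
            "age_band": ("under18", "18_44", "45_64", "65_plus",
                         "not_specified"),
            "seriousness": ("serious", "non_serious"),
        }[self.axis]


def _pt_report_counts(cases: Iterable[ReportCase]) -> Counter:
    counts: Counter = Counter()
    for case in cases:
        counts.update(case.distinct_pts)
    return counts


def _check_subset(cohort, background):
    cohort_ids = {c.primaryid for c in cohort}
    background_ids = {c.primaryid for c in background}
    if not cohort_ids <= background_ids:
        raise ValidationError(
            "cohort is not a subset of the background "
            f"({len(cohort_ids - background_ids)} cases missing)"
        )
    return cohort_ids, background_ids


def build_contingency(cohort: list, background: list,
                      pt: str) -> ContingencyTable:
    """Build the 2x2 table for one PT: cohort vs rest-of-background.

    Counting is report-level (a report with the PT repeated still counts
    once). The background must contain the cohort.
    """
    cohort_ids, _ = _check_subset(cohort, background)
    a = sum(1 for case in cohort if pt in case.distinct_pts)
    c = sum(1 for case in background
            if case.primaryid not in cohort_ids and pt in case.distinct_pts)
    b = len(cohort) - a
    d = len(background) - len(cohort) - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def run_screen(cohort: list, background: list, meddra: MeddraDict,
               thresholds: SignalThresholds = SignalThresholds(),
               min_a: int = 3,
               comparator_mode: str = "full_database",
               prior: Optional[GPSPrior] = None) -> ScreenResult:
    """Screen every PT reported at least ``min_a`` times in the cohort.

    The MGPS prior is fitted once on the (a, E) cells of *all* PTs with
    a >= 1 (the wider set stabilizes the empirical prior), then applied to
    every screened row. Deterministic given inputs and invariant to input
    case ordering. Rows are sorted by descending report count, ties broken
    alphabetically by PT.
    """
    if min_a < 1:
        raise ValidationError("min_a must be at least 1")
    cohort, background = list(cohort), list(background)
    if not cohort:
        return ScreenResult(rows=[], background_size=len(background),
                            cohort_size=0, thresholds=thresholds,
                            comparator_mode=comparator_mode)
    cohort_ids, _ = _check_subset(cohort, background)

    a_counts = _pt_report_counts(cohort)
    rest = [case for case in background if case.primaryid not in cohort_ids]
    c_counts = _pt_report_counts(rest)

    missing = [pt for pt in a_counts if pt not in meddra]
    if missing:
        raise UnmappedTermError(missing)

    n_cohort, n_bg = len(cohort), len(background)
    tables = {}
    for pt, a in a_counts.items():
        c = c_counts.get(pt, 0)
        tables[pt] = ContingencyTable(a=a, b=n_cohort - a, c=c,
                                      d=n_bg - n_cohort - c)
    if prior is None:
        cells = [(t.a, t.expected) for t in tables.values()]
        prior = mgps_fit_prior(cells)

    rows = [
        ScreenRow(pt=pt, soc=meddra.soc_of(pt), table=t,
                  metrics=compute_metrics(t, prior=prior,
                                          thresholds=thresholds))
        for pt, t in tables.items() if t.a >= min_a
    ]
    rows.sort(key=lambda r: (-r.table.a, r.pt))
    return ScreenResult(rows=rows, background_size=n_bg,
                        cohort_size=n_cohort, thresholds=thresholds,
                        comparator_mode=comparator_mode, prior=prior)


def rank_top(result: ScreenResult, k: int,
             key: str = "frequency") -> list:
    """Top-k screen rows by frequency, signal count, or signal strength.

    ``frequency`` ranks by report count a; ``signal_count`` by the number
    of algorithms flagging, then a; ``strength`` by EBGM then ROR. Ties
    always break alphabetically by PT, so rankings are stable across runs.
    """
    def n_flags(r):
        return sum(bool(r.metrics.flags.get(alg))
                   for alg in ("ror", "prr", "bcpnn", "mgps"))

    if key == "frequency":
        sort_key = lambda r: (-r.table.a, r.pt)
    elif key == "signal_count":
        sort_key = lambda r: (-n_flags(r), -r.table.a, r.pt)
    elif key == "strength":
        sort_key = lambda r: (-(r.metrics.ebgm or 0.0), -r.metrics.ror, r.pt)
    else:
        raise ValidationError(f"unknown ranking key {key!r}")
    return sorted(result.rows, key=sort_key)[: max(k, 0)]


def subgroup_screen(cohort: list, background: list, spec: SubgroupSpec,
                    meddra: MeddraDict,
                    thresholds: SignalThresholds = SignalThresholds(),
                    min_a: int = 3, min_cohort: int = 10,
                    comparator_mode: str = "full_database") -> dict:
    """One screen per stratum, cohort and background both restricted.

    Levels whose cohort stratum is below ``min_cohort`` are returned as
    skipped results (empty row list, ``skipped=True``) rather than fitted
    on noise.
    """
    results = {}
    for level in spec.levels:
        sub_cohort = [c for c in cohort if spec.level_of(c) == level]
        sub_background = [c for c in background if spec.level_of(c) == level]
        if len(sub_cohort) < min_cohort:
            results[level] = ScreenResult(
                rows=[], background_size=len(sub_background),
                cohort_size=len(sub_cohort), thresholds=thresholds,
                comparator_mode=comparator_mode, skipped=True,
                skip_reason=f"cohort stratum below {min_cohort} cases",
            )
            continue
        results[level] = run_screen(
            sub_cohort, sub_background, meddra, thresholds=thresholds,
            min_a=min_a, comparator_mode=comparator_mode,
        )
    return results


def heatmap_matrix(results: dict, top_k: int = 30,
                   metric: str = "ic") -> tuple:
    """PT x level matrices of a chosen metric and of report counts.

    The row set is the union of each level's top-``top_k`` PTs by report
    count; a PT absent from a level's screen appears as a missing value
    (NaN) in that column. Returns ``(metric_frame, count_frame)``.
    """
    pts = set()
    for res in results.values():
        if res.skipped:
            continue
        pts.update(r.pt for r in rank_top(res, top_k, key="frequency"))
    pts = sorted(pts)
    levels = list(results)

    metric_df = pd.DataFrame(np.nan, index=pts, columns=levels)
    count_df = pd.DataFrame(np.nan, index=pts, columns=levels)
    for level, res in results.items():
        if res.skipped:
            continue
        for row in res.rows:
            if row.pt in metric_df.index:
                metric_df.loc[row.pt, level] = getattr(row.metrics, metric)
                count_df.loc[row.pt, level] = row.table.a
    metric_df.index.name = "pt"
    count_df.index.name = "pt"
    return metric_df, count_df


def screen_to_frame(result: ScreenResult) -> pd.DataFrame:
    """Flatten a screen into the standard delimited-output column layout."""
    records = []
    for r in result.rows:
        m = r.metrics
        records.append({
            "pt": r.pt, "soc": r.soc,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": m.ror, "ror_lo95": m.ror_lo95, "ror_hi95": m.ror_hi95,
            "prr": m.prr, "prr_chi2": m.prr_chi2,
            "ic": m.ic, "ic025": m.ic025, "ic975": m.ic975,
            "ebgm": m.ebgm, "eb05": m.eb05,
            "flag_ror": m.flags.get("ror", False),
            "flag_prr": m.flags.get("prr", False),
            "flag_bcpnn": m.flags.get("bcpnn", False),
            "flag_mgps": m.flags.get("mgps", False),
            "flag_any": m.flags.get("any", False),
            "flag_all_four": m.flags.get("all_four", False),
        })
    return pd.DataFrame(records, columns=SCREEN_COLUMNS)
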