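"""Case deduplication, drug-name standardization and value recoding.

Spontaneous-report databases accumulate several submitted versions per
case (follow-ups and outright duplicates). Analyses keep the most recent
version of each case: latest report date, ties broken by the greatest
primaryid — numerically when both ids are numeric, lexically otherwise.
The result is deterministic for any input ordering, and running the
deduplication twice changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Tuple

from .errors import DataError, ValidationError
from .records import UNMATCHED, ReportCase

log = logging.getLogger(__name__)

__all__ = [
    "SynonymMap", "CleaningReport", "Bounds",
    "deduplicate", "standardize_drug", "standardize_cases",
    "recode_implausible", "recode_cases", "harmonize_age",
    "load_synonym_maps", "clean_cases",
]

#: Age-unit conversion factors to years.
_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


@dataclass
class SynonymMap:
    """Maps trade names, salt forms and misspellings to one canonical name.

    Matching is exact after trimming and case-folding; no fuzzy matching,
    so case selection stays auditable.
    """

    canonical_name: str
    synonyms: frozenset

    @classmethod
    def build(cls, canonical: str, synonyms: Iterable[str]) -> "SynonymMap":
        folded = frozenset(s.strip().casefold() for s in synonyms)
        folded |= {canonical.strip().casefold()}
        return cls(canonical_name=canonical, synonyms=folded)


@dataclass
class CleaningReport:
    """Counts reconciling input and output of the cleaning stage."""

    input_cases: int = 0
    duplicates_removed: int = 0
    values_recoded: dict = field(default_factory=dict)
    output_cases: int = 0

    def check(self) -> None:
        if self.output_cases != self.input_cases - self.duplicates_removed:
            raise DataError("cleaning report counts do not reconcile")


@dataclass(frozen=True)
class Bounds:
    """Plausibility bounds; values outside are recoded as missing."""

    age_years: Tuple[float, float] = (0.0, 120.0)
    weight_kg: Tuple[float, float] = (2.0, 400.0)


def _pid_sort_key(primaryid: str):
    # numeric ids compare numerically and sort above non-numeric ones
    pid = primaryid.strip()
    if pid.isdigit():
        return (1, int(pid), "")
    return (0, 0, pid)


def _version_key(case: ReportCase):
    d = case.report_date or date.min
    return (d, _pid_sort_key(case.primaryid))


def deduplicate(cases: Iterable[ReportCase]):
    """Keep one version per caseid: latest report date, then greatest primaryid.

    Returns ``(kept_cases, CleaningReport)``. Output order is deterministic
    (sorted by caseid) regardless of input order; idempotent.
    """
    cases = list(cases)
    best: dict = {}
    for case in cases:
        if not case.caseid or not case.primaryid:
            raise DataError(f"case without caseid/primaryid: {case!r}")
        cur = best.get(case.caseid)
        if cur is None or _version_key(case) > _version_key(cur):
            best[case.caseid] = case
    kept = [best[cid] for cid in sorted(best, key=_pid_sort_key)]
    report = CleaningReport(
        input_cases=len(cases),
        duplicates_removed=len(cases) - len(kept),
        output_cases=len(kept),
    )
    report.check()
    return kept, report


def standardize_drug(raw_name: str, maps: Iterable[SynonymMap]) -> str:
    """Exact-match lookup of a reported drug name against the synonym maps.

    Returns the canonical name, or :data:`~pvsignal.records.UNMATCHED`
    when no synonym matches (never a fuzzy guess).
    """
    if not raw_name or not raw_name.strip():
        raise ValidationError("drug name must be non-empty")
    key = raw_name.strip().casefold()
    for m in maps:
        if key in m.synonyms:
            return m.canonical_name
    return UNMATCHED


def standardize_cases(cases, maps):
    """Fill ``name_canonical`` on every drug entry of every case (in place)."""
    maps = list(maps)
    _check_disjoint(maps)
    lookup = {}
    for m in maps:
        for s in m.synonyms:
            lookup[s] = m.canonical_name
    for case in cases:
        for entry in case.drugs:
            key = entry.name_raw.strip().casefold()
            entry.name_canonical = lookup.get(key, UNMATCHED)
    return cases


def _check_disjoint(maps):
    seen = {}
    for m in maps:
        for s in m.synonyms:
            if s in seen and seen[s] != m.canonical_name:
                raise ValidationError(
                    f"synonym {s!r} claimed by both {seen[s]!r} "
                    f"and {m.canonical_name!r}"
                )
            seen[s] = m.canonical_name


def recode_implausible(case: ReportCase, rules: Bounds = Bounds()):
    """Recode implausible values as missing; never alter plausible ones.

    Negative onset intervals, ages outside the configured band and weights
    outside the configured band become missing. Returns
    ``(new_case, counts_by_field)``.
    """
    changes = {}
    counts = {}
    if case.onset_days is not None and case.onset_days < 0:
        changes["onset_days"] = None
        counts["onset_days"] = 1
    lo, hi = rules.age_years
    if case.age_years is not None and not (lo <= case.age_years <= hi):
        changes["age_years"] = None
        counts["age_years"] = 1
    lo, hi = rules.weight_kg
    if case.weight_kg is not None and not (lo <= case.weight_kg <= hi):
        changes["weight_kg"] = None
        counts["weight_kg"] = 1
    return (replace(case, **changes) if changes else case), counts


def recode_cases(cases, rules: Bounds = Bounds()):
    """Apply :func:`recode_implausible` to every case; totals per field."""
    out, totals = [], {}
    for case in cases:
        new, counts = recode_implausible(case, rules)
        out.append(new)
        for k, v in counts.items():
            totals[k] = totals.get(k, 0) + v
    return out, totals


def harmonize_age(value: float, unit_code: str) -> Optional[float]:
    """Convert a reported age to years given its unit code.

    DEC is decades, MON months, WK weeks, DY days, HR hours; YR identity.
    Unknown unit codes yield missing (with a warning) rather than a guess.
    """
    if value is None:
        return None
    if value < 0:
        raise ValidationError("age value must be non-negative")
    factor = _AGE_FACTORS.get((unit_code or "").strip().upper())
    if factor is None:
        log.warning("unknown age unit code %r; age treated as missing",
                    unit_code)
        return None
    return value * factor


def load_synonym_maps(path, delimiter: str = "\t"):
    """Load synonym maps from a two-column file: canonical, synonym."""
    groups: dict = {}
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(delimiter)
        if len(parts) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 columns")
        canonical, synonym = (p.strip() for p in parts)
        groups.setdefault(canonical, set()).add(synonym)
    maps = [SynonymMap.build(c, syns) for c, syns in sorted(groups.items())]
    _check_disjoint(maps)
    return maps


def clean_cases(cases, synonym_maps=(), bounds: Bounds = Bounds()):
    """Full cleaning pass: standardize, recode, deduplicate.

    Returns ``(cases, CleaningReport)`` with the recode totals folded into
    the report.
    """
    cases = list(cases)
    if synonym_maps:
        standardize_cases(cases, synonym_maps)
    cases, recode_totals = recode_cases(cases, bounds)
    kept, report = deduplicate(cases)
    report.values_recoded = recode_totals
    return kept, report
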