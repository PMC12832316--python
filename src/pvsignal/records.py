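"""Core record types for spontaneous safety reports.

A *case* is one deduplicated safety report identified by a ``caseid``;
each submitted version of a case carries its own ``primaryid``. Identifiers
are opaque strings throughout (leading zeros occur in real data and must
survive round trips).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Optional

__all__ = [
    "OUTCOME_CODES",
    "SERIOUS_OUTCOMES",
    "SEX_LEVELS",
    "REPORTER_LEVELS",
    "DrugEntry",
    "ReportCase",
    "EventRecord",
    "MeddraDict",
    "UNMATCHED",
]

#: Regulatory outcome codes -> canonical outcome names.
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other",
}

#: Outcomes that make a report "serious" under the regulatory definition.
SERIOUS_OUTCOMES = frozenset(
    {"death", "life_threatening", "hospitalization", "disability",
     "congenital_anomaly", "required_intervention"}
)

SEX_LEVELS = ("F", "M", "unknown")

REPORTER_LEVELS = (
    "consumer",
    "physician",
    "pharmacist",
    "other_health_professional",
    "not_specified",
)

#: Marker returned by drug-name standardization when no synonym matches.
UNMATCHED = "__unmatched__"


@dataclass
class DrugEntry:
    """One drug row attached to a report.

    ``name_raw`` is the verbatim reported name; ``name_canonical`` is filled
    by exact-match standardization (or set to :data:`UNMATCHED`). ``role``
    uses the standard codes: PS (primary suspect), SS (secondary suspect),
    C (concomitant), I (interacting). ``indication_pt`` is the indication
    preferred term attached to *this* drug entry, if any.
    """

    name_raw: str
    role: str
    indication_pt: Optional[str] = None
    name_canonical: Optional[str] = None

    @property
    def name(self) -> str:
        """Canonical name when standardized, else the raw name."""
        if self.name_canonical and self.name_canonical != UNMATCHED:
            return self.name_canonical
        return self.name_raw


@dataclass
class ReportCase:
    """One safety report (one version; deduplication keeps one per caseid)."""

    primaryid: str
    caseid: str
    report_date: Optional[date] = None
    event_date: Optional[date] = None
    age_years: Optional[float] = None
    sex: str = "unknown"
    weight_kg: Optional[float] = None
    reporter: str = "not_specified"
    country_occur: Optional[str] = None
    country_report: Optional[str] = None
    serious_flag: bool = False
    outcomes: frozenset = field(default_factory=frozenset)
    drugs: list = field(default_factory=list)
    events: list = field(default_factory=list)
    therapy_start: Optional[date] = None
    onset_days: Optional[float] = None

    @property
    def serious(self) -> bool:
        """Serious if any serious outcome is listed or the source flag is set.

        The flag and the outcome set are tracked independently: real
        summaries report both a seriousness classification and an outcome
        breakdown, and the two need not reconcile exactly.
        """
        return self.serious_flag or bool(self.outcomes & SERIOUS_OUTCOMES)

    @property
    def distinct_pts(self) -> tuple:
        """Distinct event PTs in first-occurrence order."""
        return tuple(dict.fromkeys(self.events))

    def with_(self, **changes) -> "ReportCase":
        return replace(self, **changes)


@dataclass(frozen=True)
class EventRecord:
    """One event-level record: a (report, preferred term) pair with its SOC."""

    primaryid: str
    pt: str
    soc: str


@dataclass
class MeddraDict:
    """A PT -> SOC dictionary (a stand-in for the licensed terminology).

    Must be a total function on the PT vocabulary in use: every preferred
    term maps to exactly one system organ class.
    """

    pt_to_soc: dict
    version_label: str = "synthetic"

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc[pt]

    def __contains__(self, pt: str) -> bool:
        return pt in self.pt_to_soc
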