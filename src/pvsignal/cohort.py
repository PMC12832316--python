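"""Cohort selection, event-level expansion and derived analysis variables.

A cohort is the set of cleaned reports in which the study drug is listed
as a suspect (primary or secondary) with the study indication attached to
that drug entry. Indication matching is at the case-drug level: the
indication must be attached to the suspect-drug entry itself, not to any
drug on the report.

Reports may list several preferred terms; analyses of event distributions
treat each distinct (report, PT) pair as one event-level record.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Set

from .errors import UnmappedTermError, ValidationError
from .records import EventRecord, MeddraDict, ReportCase

__all__ = [
    "select_cohort", "expand_events", "assign_age_band",
    "compute_onset_days", "onset_band", "load_meddra_dict",
    "write_meddra_dict", "AGE_BANDS", "ONSET_BANDS",
]

AGE_BANDS = ("under18", "18_44", "45_64", "65_plus", "not_specified")

ONSET_BANDS = ("0_30", "31_60", "61_90", "91_120", "121_150",
               "151_180", "181_360", "over_360", "missing")


def select_cohort(cases: Iterable[ReportCase], drug: str,
                  indication_terms: Set[str],
                  adult_only: bool = False) -> list:
    """Select reports with the drug as suspect for the given indication.

    Retains cases where some drug entry has the canonical drug name, role
    PS or SS, and an indication PT in ``indication_terms``. With
    ``adult_only`` cases with age below 18 are dropped; missing age is
    retained (real spontaneous data has large not-specified fractions, and
    dropping them would silently discard most of a cohort). Order-preserving.
    """
    if not indication_terms:
        raise ValidationError("indication_terms must be non-empty")
    drug_key = drug.strip().casefold()
    ind_keys = {t.strip().casefold() for t in indication_terms}

    selected = []
    for case in cases:
        hit = any(
            entry.name.strip().casefold() == drug_key
            and entry.role in ("PS", "SS")
            and entry.indication_pt is not None
            and entry.indication_pt.strip().casefold() in ind_keys
            for entry in case.drugs
        )
        if not hit:
            continue
        if adult_only and case.age_years is not None and case.age_years < 18:
            continue
        selected.append(case)
    return selected


def expand_events(cohort: Iterable[ReportCase],
                  meddra: MeddraDict) -> list:
    """Expand reports to event-level records: one per (case, distinct PT).

    Within-case repeats of the same PT collapse to a single record (repeats
    arise from follow-up merges and must not double-count). Every PT must
    map to a SOC; unmapped terms raise, listing the misses.
    """
    cohort = list(cohort)
    missing = {pt for case in cohort for pt in case.distinct_pts
               if pt not in meddra}
    if missing:
        raise UnmappedTermError(missing)
    return [
        EventRecord(primaryid=case.primaryid, pt=pt, soc=meddra.soc_of(pt))
        for case in cohort
        for pt in case.distinct_pts
    ]


def assign_age_band(age_years: Optional[float]) -> str:
    """Assign the standard analysis age band; missing -> not_specified."""
    if age_years is None:
        return "not_specified"
    if age_years < 18:
        return "under18"
    if age_years < 45:
        return "18_44"
    if age_years < 65:
        return "45_64"
    return "65_plus"


def compute_onset_days(therapy_start: Optional[date],
                       event_date: Optional[date]) -> Optional[int]:
    """Days from therapy start to event onset; missing endpoints -> missing.

    Negative differences are data errors (onset before therapy start) and
    are reported as missing, mirroring the implausible-value recoding rule.
    """
    if therapy_start is None or event_date is None:
        return None
    days = (event_date - therapy_start).days
    return days if days >= 0 else None


def onset_band(days: Optional[float]) -> str:
    """Band a time-to-onset in days into the standard closed intervals."""
    if days is None:
        return "missing"
    if days < 0:
        return "missing"
    for hi, label in ((30, "0_30"), (60, "31_60"), (90, "61_90"),
                      (120, "91_120"), (150, "121_150"), (180, "151_180"),
                      (360, "181_360")):
        if days <= hi:
            return label
    return "over_360"


def load_meddra_dict(path, delimiter: str = "\t") -> MeddraDict:
    """Load a PT->SOC dictionary from a two-column file.

    An optional first line ``# version: <label>`` carries the version label.
    """
    pt_to_soc = {}
    version = "unversioned"
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if line.startswith("# version:"):
            version = line.split(":", 1)[1].strip()
            continue
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(delimiter)
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns")
        pt, soc = (p.strip() for p in parts)
        if pt in pt_to_soc and pt_to_soc[pt] != soc:
            raise ValidationError(
                f"{path}:{lineno}: PT {pt!r} mapped to two SOCs")
        pt_to_soc[pt] = soc
    return MeddraDict(pt_to_soc=pt_to_soc, version_label=version)


def write_meddra_dict(meddra: MeddraDict, path, delimiter: str = "\t") -> None:
    lines = [f"# version: {meddra.version_label}"]
    lines += [f"{pt}{delimiter}{soc}"
              for pt, soc in sorted(meddra.pt_to_soc.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
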