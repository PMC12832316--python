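"""Reading, writing and assembly of FAERS-style quarterly ASCII tables.

The quarterly bundles follow the public FAERS ASCII dialect: one file per
table kind ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR"),
``$``-delimited, a single header row, no quoting. Values are preserved
verbatim as strings; identifiers are never coerced to integers. Files are
decoded as Latin-1 with replacement because real archives contain
non-UTF-8 bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional

from .cleaning import harmonize_age
from .errors import DataError, SchemaError
from .records import OUTCOME_CODES, DrugEntry, ReportCase

log = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

#: Declared column schema per table kind (versioned registry, v1).
#: Unknown extra columns found in files are carried through untouched —
#: the public schemas drift across quarters.
SCHEMA_REGISTRY_VERSION = "v1"
TABLE_SCHEMAS = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "wt", "wt_cod", "occp_cod", "occr_country",
        "reporter_country", "serious",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
    "RPSR": ["primaryid", "caseid", "rpsr_cod"],
}

#: Columns that must be present for a file of a given kind to be usable.
MANDATORY_COLUMNS = {
    "DEMO": ("primaryid", "caseid"),
    "DRUG": ("primaryid", "drugname"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid",),
    "INDI": ("primaryid",),
    "RPSR": ("primaryid",),
}

DEFAULT_DELIMITER = "$"

_OCCP_MAP = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health_professional",
    "HP": "other_health_professional",
    "RN": "other_health_professional",
    "LW": "not_specified",
}


@dataclass
class RawTableRow:
    """One as-read row of a quarterly table; values untyped strings."""

    table_kind: str
    payload: dict

    def __post_init__(self):
        if self.table_kind not in TABLE_KINDS:
            raise SchemaError(f"unknown table kind {self.table_kind!r}")

    @property
    def primaryid(self) -> str:
        return self.payload.get("primaryid", "")

    @property
    def caseid(self) -> str:
        return self.payload.get("caseid", "")


@dataclass
class QuarterBundle:
    """All seven tables of one quarterly release."""

    quarter_label: str
    tables: dict = field(default_factory=lambda: {k: [] for k in TABLE_KINDS})

    def __post_init__(self):
        for kind in TABLE_KINDS:
            self.tables.setdefault(kind, [])

    def rows(self, kind: str) -> list:
        return self.tables[kind]


@dataclass
class AssemblyResult:
    """Assembled cases plus the bookkeeping the join produced."""

    cases: list
    orphan_count: int
    orphans_by_kind: dict
    demo_duplicates: int

    def __iter__(self):
        return iter(self.cases)

    def __len__(self):
        return len(self.cases)


def read_ascii_table(path, kind: str, delimiter: str = DEFAULT_DELIMITER) -> list:
    """Read one ``$``-delimited ASCII table into :class:`RawTableRow` rows.

    Column values are preserved verbatim, including empty strings. A file
    with a header and no data lines yields an empty list.
    """
    if kind not in TABLE_KINDS:
        raise SchemaError(f"unknown table kind {kind!r}")
    path = Path(path)
    with open(path, "r", encoding="latin-1", errors="replace", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file, no header row")
        columns = header_line.rstrip("\r\n").split(delimiter)
        for col in MANDATORY_COLUMNS[kind]:
            if col not in columns:
                raise SchemaError(
                    f"{path}: {kind} table is missing mandatory column {col!r}"
                )
        ncol = len(columns)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if line == "":
                continue
            values = line.split(delimiter)
            if len(values) != ncol:
                raise SchemaError(
                    f"{path}:{lineno}: expected {ncol} fields, got {len(values)}"
                )
            payload = dict(zip(columns, values))
            if not payload.get("primaryid"):
                raise SchemaError(f"{path}:{lineno}: empty primaryid")
            rows.append(RawTableRow(kind, payload))
    return rows


def write_ascii_table(rows: Iterable[RawTableRow], path,
                      delimiter: str = DEFAULT_DELIMITER,
                      kind: Optional[str] = None) -> None:
    """Write rows as a ``$``-delimited ASCII table (header + one line per row).

    Re-reading the written file reproduces the rows exactly. There is no
    quoting dialect: a payload value containing the delimiter is an error.
    For zero rows, ``kind`` selects the header to emit.
    """
    rows = list(rows)
    if rows:
        kinds = {r.table_kind for r in rows}
        if len(kinds) > 1:
            raise DataError(f"rows mix table kinds: {sorted(kinds)}")
        kind = kinds.pop()
    elif kind is None:
        raise DataError("empty row list needs an explicit table kind")

    declared = TABLE_SCHEMAS[kind]
    columns = list(declared)
    for row in rows:
        for key in row.payload:
            if key not in columns:
                columns.append(key)
    # drop declared columns absent from every row (schema drift tolerance)
    if rows:
        present = set().union(*(r.payload.keys() for r in rows))
        columns = [c for c in columns if c in present]

    with open(path, "w", encoding="latin-1", newline="") as fh:
        fh.write(delimiter.join(columns) + "\n")
        for row in rows:
            values = []
            for col in columns:
                v = row.payload.get(col, "")
                if delimiter in v:
                    raise DataError(
                        f"value {v!r} in column {col!r} contains the "
                        f"delimiter {delimiter!r}; FAERS ASCII has no quoting"
                    )
                values.append(v)
            fh.write(delimiter.join(values) + "\n")


def write_bundle(bundle: QuarterBundle, out_dir,
                 delimiter: str = DEFAULT_DELIMITER) -> dict:
    """Write all seven tables of a bundle as ``<KIND><quarter>.txt`` files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in TABLE_KINDS:
        path = out_dir / f"{kind}{bundle.quarter_label}.txt"
        write_ascii_table(bundle.rows(kind), path, delimiter=delimiter, kind=kind)
        paths[kind] = path
    return paths


def read_bundle(data_dir, quarter_label: str,
                delimiter: str = DEFAULT_DELIMITER) -> QuarterBundle:
    """Read one quarter's seven tables from ``<KIND><quarter>.txt`` files."""
    data_dir = Path(data_dir)
    tables = {}
    for kind in TABLE_KINDS:
        path = data_dir / f"{kind}{quarter_label}.txt"
        tables[kind] = read_ascii_table(path, kind, delimiter=delimiter) \
            if path.exists() else []
    return QuarterBundle(quarter_label, tables)


def parse_faers_date(value: str) -> Optional[date]:
    """Parse a ``YYYYMMDD`` date string; partial or malformed dates -> None."""
    value = (value or "").strip()
    if len(value) != 8 or not value.isdigit():
        return None
    try:
        return datetime.strptime(value, "%Y%m%d").date()
    except ValueError:
        return None


def _parse_float(value: str) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _parse_weight(wt: str, wt_cod: str) -> Optional[float]:
    value = _parse_float(wt)
    if value is None:
        return None
    unit = (wt_cod or "KG").strip().upper()
    if unit in ("", "KG", "KGS"):
        return value
    if unit in ("LBS", "LB"):
        return value * 0.45359237
    if unit in ("GMS", "G"):
        return value / 1000.0
    log.warning("unknown weight unit %r; treating value as missing", wt_cod)
    return None


def assemble_cases(bundles: Iterable[QuarterBundle]) -> AssemblyResult:
    """Join the seven tables by primaryid into per-report cases.

    One :class:`~pvsignal.records.ReportCase` is produced per distinct
    primaryid that has a DEMO row; rows of other tables whose primaryid
    never appears in DEMO are *orphans* — excluded and counted. A duplicate
    primaryid within DEMO keeps the last occurrence (with a warning).
    """
    bundles = list(bundles)
    if not bundles:
        raise DataError("assemble_cases needs at least one quarterly bundle")

    demo_rows: dict = {}
    demo_duplicates = 0
    for bundle in bundles:
        seen_this_quarter = set()
        for row in bundle.rows("DEMO"):
            pid = row.primaryid
            if pid in seen_this_quarter:
                demo_duplicates += 1
                log.warning(
                    "duplicate primaryid %s in DEMO for quarter %s; "
                    "keeping last occurrence", pid, bundle.quarter_label,
                )
            seen_this_quarter.add(pid)
            demo_rows[pid] = row

    aux = {kind: {} for kind in TABLE_KINDS if kind != "DEMO"}
    orphans_by_kind = {kind: 0 for kind in TABLE_KINDS if kind != "DEMO"}
    for bundle in bundles:
        for kind in aux:
            for row in bundle.rows(kind):
                pid = row.primaryid
                if pid not in demo_rows:
                    orphans_by_kind[kind] += 1
                    continue
                aux[kind].setdefault(pid, []).append(row)

    cases = []
    for pid, demo in demo_rows.items():
        p = demo.payload
        indications = {}
        for row in aux["INDI"].get(pid, []):
            seq = row.payload.get("indi_drug_seq", "")
            pt = row.payload.get("indi_pt", "").strip()
            if pt:
                indications[seq] = pt

        drugs = []
        for row in aux["DRUG"].get(pid, []):
            rp = row.payload
            role = rp.get("role_cod", "").strip().upper()
            if role not in ("PS", "SS", "C", "I"):
                role = "C"
            drugs.append(DrugEntry(
                name_raw=rp.get("drugname", "").strip(),
                role=role,
                indication_pt=indications.get(rp.get("drug_seq", "")),
            ))

        events = [row.payload.get("pt", "").strip()
                  for row in aux["REAC"].get(pid, [])
                  if row.payload.get("pt", "").strip()]

        outcomes = frozenset(
            OUTCOME_CODES[code]
            for row in aux["OUTC"].get(pid, [])
            if (code := row.payload.get("outc_cod", "").strip().upper())
            in OUTCOME_CODES
        )

        starts = [d for row in aux["THER"].get(pid, [])
                  if (d := parse_faers_date(row.payload.get("start_dt", "")))]
        therapy_start = min(starts) if starts else None

        age = _parse_float(p.get("age", ""))
        age_years = (harmonize_age(age, p.get("age_cod", "YR") or "YR")
                     if age is not None else None)

        event_date = parse_faers_date(p.get("event_dt", ""))
        onset = None
        if therapy_start is not None and event_date is not None:
            onset = (event_date - therapy_start).days

        sex = p.get("sex", "").strip().upper()
        cases.append(ReportCase(
            primaryid=pid,
            caseid=p.get("caseid", "") or pid,
            report_date=parse_faers_date(p.get("fda_dt", "")),
            event_date=event_date,
            age_years=age_years,
            sex=sex if sex in ("F", "M") else "unknown",
            weight_kg=_parse_weight(p.get("wt", ""), p.get("wt_cod", "")),
            reporter=_OCCP_MAP.get(p.get("occp_cod", "").strip().upper(),
                                   "not_specified"),
            country_occur=p.get("occr_country", "").strip() or None,
            country_report=p.get("reporter_country", "").strip() or None,
            serious_flag=p.get("serious", "").strip().upper() in ("Y", "1"),
            outcomes=outcomes,
            drugs=drugs,
            events=events,
            therapy_start=therapy_start,
            onset_days=onset,
        ))

    return AssemblyResult(
        cases=cases,
        orphan_count=sum(orphans_by_kind.values()),
        orphans_by_kind=orphans_by_kind,
        demo_duplicates=demo_duplicates,
    )
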