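"""End-to-end orchestration: clean and analyze runs over quarterly data.

Every run writes a resolved-configuration snapshot and a manifest next to
its outputs so results are reproducible from (inputs, config) alone.
Counts are logged at each stage and reconcile across stages (raw ->
deduplicated -> eligible), mirroring the attrition flowcharts of
pharmacovigilance reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .cleaning import Bounds, CleaningReport, clean_cases, load_synonym_maps
from .cohort import (expand_events, load_meddra_dict, select_cohort)
from .descriptives import (compare_categorical, soc_distribution,
                           summarize_categorical, summarize_continuous)
from .dispro import SignalThresholds
from .errors import DataError, ValidationError
from .faers_io import assemble_cases, read_bundle
from .records import ReportCase
from .screen import (SubgroupSpec, heatmap_matrix, run_screen,
                     screen_to_frame, subgroup_screen)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "cmd_clean", "cmd_analyze",
           "save_case_store", "load_case_store"]


@dataclass
class RunConfig:
    """Structured configuration for a pipeline run."""

    data_dir: str
    out_dir: str
    quarters: Tuple[str, ...] = ()
    delimiter: str = "$"
    drugs: Tuple[str, ...] = ()
    synonym_file: Optional[str] = None
    meddra_file: Optional[str] = None
    indication_terms: Tuple[str, ...] = ("Alopecia areata",)
    adult_only: bool = True
    require_complete: bool = False   # drop reports missing age/sex/onset
    comparator_mode: str = "full_database"
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    subgroup_axes: Tuple[str, ...] = ("gender", "age_band", "seriousness")
    min_a: int = 3
    heatmap_top_k: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        th = raw.pop("thresholds", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if th:
            cfg.thresholds = SignalThresholds(**th)
        return cfg

    def validate(self) -> None:
        if not Path(self.data_dir).is_dir():
            raise ValidationError(f"data_dir {self.data_dir!r} does not exist")
        for attr in ("synonym_file", "meddra_file"):
            p = getattr(self, attr)
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"{attr} {p!r} does not exist")
        if not self.indication_terms:
            raise ValidationError("indication_terms must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_resolved_config(config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8")


def _manifest(out_dir: Path, extra: dict) -> None:
    files = {}
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out_dir))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    payload = {"pvsignal_version": __version__, "files": files, **extra}
    (out_dir / "manifest.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def _case_to_json(case: ReportCase) -> dict:
    d = dataclasses.asdict(case)
    for k in ("report_date", "event_date", "therapy_start"):
        if d[k] is not None:
            d[k] = d[k].isoformat()
    d["outcomes"] = sorted(case.outcomes)
    return d


def _case_from_json(d: dict) -> ReportCase:
    from .records import DrugEntry
    for k in ("report_date", "event_date", "therapy_start"):
        if d[k] is not None:
            d[k] = date.fromisoformat(d[k])
    d["outcomes"] = frozenset(d["outcomes"])
    d["drugs"] = [DrugEntry(**e) for e in d["drugs"]]
    return ReportCase(**d)


def save_case_store(cases, path) -> None:
    """Write cleaned cases as JSON lines (one report per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for case in cases:
            fh.write(json.dumps(_case_to_json(case), sort_keys=True) + "\n")


def load_case_store(path) -> list:
    with open(path, "r", encoding="utf-8") as fh:
        return [_case_from_json(json.loads(line)) for line in fh if line.strip()]


def cmd_clean(config: RunConfig):
    """Ingest, standardize, recode and deduplicate; write the cleaned store.

    Emits ``cases.jsonl``, ``cleaning_report.json`` and an attrition
    ledger ``attrition.tsv`` (raw -> assembled -> deduplicated).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    _write_resolved_config(config, out_dir)

    quarters = config.quarters
    if not quarters:
        # discover quarters from DEMO file names
        quarters = tuple(sorted(
            p.name[len("DEMO"):-len(".txt")]
            for p in Path(config.data_dir).glob("DEMO*.txt")))
        if not quarters:
            raise ValidationError(
                f"no DEMO*.txt files found under {config.data_dir!r}")

    bundles = [read_bundle(config.data_dir, q, delimiter=config.delimiter)
               for q in quarters]
    raw_rows = sum(len(b.rows("DEMO")) for b in bundles)
    assembly = assemble_cases(bundles)
    log.info("assembled %d cases (%d orphan rows excluded)",
             len(assembly.cases), assembly.orphan_count)

    maps = (load_synonym_maps(config.synonym_file)
            if config.synonym_file else ())
    cases, report = clean_cases(assembly.cases, synonym_maps=maps,
                                bounds=Bounds())

    dropped_incomplete = 0
    if config.require_complete:
        complete = [c for c in cases
                    if c.age_years is not None and c.sex in ("F", "M")
                    and c.onset_days is not None]
        dropped_incomplete = len(cases) - len(complete)
        cases = complete

    save_case_store(cases, out_dir / "cases.jsonl")
    report_dict = dataclasses.asdict(report)
    report_dict["orphan_rows_excluded"] = assembly.orphan_count
    report_dict["dropped_incomplete"] = dropped_incomplete
    (out_dir / "cleaning_report.json").write_text(
        json.dumps(report_dict, indent=2, sort_keys=True), encoding="utf-8")

    attrition = pd.DataFrame([
        ("raw DEMO rows", raw_rows),
        ("assembled cases", report.input_cases),
        ("after deduplication", report.output_cases),
        ("after completeness filter", len(cases)),
    ], columns=["stage", "count"])
    attrition.to_csv(out_dir / "attrition.tsv", sep="\t", index=False)
    _manifest(out_dir, {"stage": "clean", "seed": config.seed})
    return cases, report


def _table1(cohorts: dict, out_dir: Path) -> None:
    blocks = []
    sex = summarize_categorical(cohorts, "sex", levels=["F", "M", "unknown"])
    blocks.append(("sex", sex.table))
    from .cohort import assign_age_band, onset_band
    age_band = summarize_categorical(
        cohorts, lambda c: assign_age_band(c.age_years),
        levels=["under18", "18_44", "45_64", "65_plus", "not_specified"])
    blocks.append(("age_band", age_band.table))
    reporter = summarize_categorical(cohorts, "reporter")
    blocks.append(("reporter", reporter.table))
    serious = summarize_categorical(
        cohorts, lambda c: "serious" if c.serious else "non_serious",
        levels=["non_serious", "serious"])
    blocks.append(("seriousness", serious.table))
    onset = summarize_categorical(
        cohorts, lambda c: onset_band(c.onset_days))
    blocks.append(("onset_band", onset.table))

    frames = []
    for name, df in blocks:
        df = df.copy()
        df.insert(0, "block", name)
        frames.append(df.reset_index())
    pd.concat(frames, axis=0).to_csv(
        out_dir / "table1_categorical.tsv", sep="\t", index=False)

    cont_rows = []
    for group, cases in cohorts.items():
        for label, values in (
                ("age_years", [c.age_years for c in cases]),
                ("onset_days", [c.onset_days for c in cases]),
                ("weight_kg", [c.weight_kg for c in cases])):
            s = summarize_continuous(values)
            cont_rows.append({"group": group, "variable": label,
                              **dataclasses.asdict(s)})
    pd.DataFrame(cont_rows).to_csv(
        out_dir / "table1_continuous.tsv", sep="\t", index=False)


def cmd_analyze(config: RunConfig):
    """Descriptives, whole-cohort screens and subgroup outputs for each drug.

    Needs a cleaned store (``cases.jsonl``) under ``out_dir`` — run
    :func:`cmd_clean` first. Writes Table-1/Table-2 style summaries, the
    seriousness comparison test, per-drug screen tables, per-axis subgroup
    screens, heatmap matrices and the run manifest.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    store = out_dir / "cases.jsonl"
    if not store.is_file():
        raise ValidationError(f"cleaned case store {store} not found; "
                              "run the clean stage first")
    if not config.drugs:
        raise ValidationError("no study drugs configured")
    if config.meddra_file is None:
        raise ValidationError("meddra_file is required for analysis")
    _write_resolved_config(config, out_dir)

    cases = load_case_store(store)
    meddra = load_meddra_dict(config.meddra_file)
    indication = set(config.indication_terms)

    # descriptive cohorts keep all ages; the signal cohorts apply the
    # adult filter (pediatric rows still appear in the descriptives, as
    # published cohort tables do)
    desc_cohorts = {d: select_cohort(cases, d, indication, adult_only=False)
                    for d in config.drugs}
    signal_cohorts = {d: select_cohort(cases, d, indication,
                                       adult_only=config.adult_only)
                      for d in config.drugs}
    for d, cohort in desc_cohorts.items():
        if not cohort:
            log.warning("empty cohort for drug %r", d)

    _table1(desc_cohorts, out_dir)

    events = {d: expand_events(c, meddra) for d, c in desc_cohorts.items()}
    for d, evs in events.items():
        soc_distribution(evs).to_csv(
            out_dir / f"table2_soc_{d}.tsv", sep="\t", index=False)

    tests = []
    if len(config.drugs) == 2:
        d1, d2 = config.drugs
        t = [[sum(1 for c in desc_cohorts[d]) -
              sum(1 for c in desc_cohorts[d] if c.serious),
              sum(1 for c in desc_cohorts[d] if c.serious)]
             for d in (d1, d2)]
        res = compare_categorical(t)
        tests.append({"comparison": "seriousness", "drug1": d1, "drug2": d2,
                      "statistic": res.statistic, "p_value": res.p_value,
                      "method": res.method, "significant": res.significant})
    if tests:
        pd.DataFrame(tests).to_csv(out_dir / "comparison_tests.tsv",
                                   sep="\t", index=False)

    for d in config.drugs:
        result = run_screen(signal_cohorts[d], cases, meddra,
                            thresholds=config.thresholds,
                            min_a=config.min_a,
                            comparator_mode=config.comparator_mode)
        screen_to_frame(result).to_csv(
            out_dir / f"screen_{d}.tsv", sep="\t", index=False)

        for axis in config.subgroup_axes:
            spec = SubgroupSpec(axis)
            sub = subgroup_screen(signal_cohorts[d], cases, spec, meddra,
                                  thresholds=config.thresholds,
                                  min_a=config.min_a,
                                  comparator_mode=config.comparator_mode)
            metric_df, count_df = heatmap_matrix(
                sub, top_k=config.heatmap_top_k)
            metric_df.to_csv(out_dir / f"heatmap_{d}_{axis}_ic.tsv", sep="\t")
            count_df.to_csv(out_dir / f"heatmap_{d}_{axis}_counts.tsv",
                            sep="\t")
            for level, res in sub.items():
                if res.skipped:
                    (out_dir / f"screen_{d}_{axis}_{level}.SKIPPED").write_text(
                        res.skip_reason + "\n", encoding="utf-8")
                else:
                    screen_to_frame(res).to_csv(
                        out_dir / f"screen_{d}_{axis}_{level}.tsv",
                        sep="\t", index=False)

    _manifest(out_dir, {
        "stage": "analyze", "seed": config.seed,
        "thresholds": config.thresholds.describe(),
        "background_size": len(cases),
        "cohort_sizes": {d: len(c) for d, c in signal_cohorts.items()},
    })
    return out_dir
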