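"""Shared fixtures: a small hand-built bundle and a generated dataset."""

from __future__ import annotations

import pytest

from pvsignal.cleaning import SynonymMap, clean_cases
from pvsignal.faers_io import QuarterBundle, RawTableRow, assemble_cases
from pvsignal.synthetic import generate, make_dictionary, scenario_jak_alopecia


def demo_row(pid, caseid=None, **extra):
    payload = {
        "primaryid": pid, "caseid": caseid or pid, "fda_dt": "20230315",
        "event_dt": "20230310", "age": "42", "age_cod": "YR", "sex": "F",
        "wt": "", "wt_cod": "", "occp_cod": "CN", "occr_country": "US",
        "reporter_country": "US", "serious": "N",
    }
    payload.update(extra)
    return RawTableRow("DEMO", payload)


def drug_row(pid, name, role="PS", seq="1", indication=None):
    return RawTableRow("DRUG", {
        "primaryid": pid, "caseid": pid, "drug_seq": seq,
        "role_cod": role, "drugname": name,
    })


def indi_row(pid, pt, seq="1"):
    return RawTableRow("INDI", {
        "primaryid": pid, "caseid": pid, "indi_drug_seq": seq, "indi_pt": pt,
    })


def reac_row(pid, pt):
    return RawTableRow("REAC", {"primaryid": pid, "caseid": pid, "pt": pt})


def make_bundle(label="2023Q1", **tables) -> QuarterBundle:
    bundle = QuarterBundle(label)
    for kind, rows in tables.items():
        bundle.tables[kind.upper()] = list(rows)
    return bundle


@pytest.fixture(scope="session")
def jak_dataset():
    """One generated JAK-alopecia dataset with its ground truth, cleaned."""
    config = scenario_jak_alopecia(seed=0)
    bundles, truth = generate(config)
    assembly = assemble_cases(bundles)
    maps = [SynonymMap.build(t.name, t.synonyms)
            for t in config.target_drugs]
    cases, report = clean_cases(assembly.cases, synonym_maps=maps)
    meddra = make_dictionary(config.n_pts, config.n_socs, config.seed)
    return {
        "config": config,
        "bundles": bundles,
        "truth": truth,
        "assembly": assembly,
        "cases": cases,
        "report": report,
        "meddra": meddra,
    }
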