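"""Synthetic FAERS-style quarterly bundles with known ground truth.

The generator emulates the structure of a spontaneous reporting database
so every pipeline stage can be exercised without any download: a
background multinomial over (drug, preferred term) with Zipf-like
marginals, implanted drug-event pairs whose joint reporting probability
is multiplied by a known factor rho and renormalized (so rho stays
interpretable as a relative reporting ratio), duplicate and follow-up
versions sharing a caseid, Table-1-like demographic structure
(sex mix, age bands, reporter type, seriousness, onset-day missingness),
and a PT->SOC dictionary built over the real system-organ-class labels.

Everything is reproducible from the seed, and the emitted ground truth
(duplicate lineage, true multipliers, per-drug cohort sizes) exactly
predicts what the cleaning and screening stages should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .faers_io import QuarterBundle, RawTableRow
from .records import MeddraDict

__all__ = [
    "SOC_LABELS", "ImplantedSignal", "TargetDrugSpec", "SynthConfig",
    "GroundTruth", "make_dictionary", "generate", "scenario_jak_alopecia",
    "scenario_signal_recovery",
]

#: The 27 system-organ-class labels of the standard terminology.
SOC_LABELS = (
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Congenital, familial and genetic disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Eye disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Nervous system disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Product issues",
    "Psychiatric disorders",
    "Renal and urinary disorders",
    "Reproductive system and breast disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Social circumstances",
    "Surgical and medical procedures",
    "Vascular disorders",
)

_AGE_BAND_RANGES = {
    "under18": (6.0, 17.9),
    "18_44": (18.0, 44.9),
    "45_64": (45.0, 64.9),
    "65_plus": (65.0, 89.0),
}

_SERIOUS_OUTCOME_CODES = ("HO", "OT", "LT", "DE", "RI", "DS")
_SERIOUS_OUTCOME_P = (0.40, 0.40, 0.07, 0.06, 0.04, 0.03)

_COUNTRIES = ("US", "JP", "DE", "FR", "CA")
_COUNTRY_P = (0.82, 0.06, 0.05, 0.04, 0.03)

_REPORTER_CODES = {
    "consumer": "CN",
    "physician": "MD",
    "pharmacist": "PH",
    "other_health_professional": "OT",
    "not_specified": "",
}


@dataclass(frozen=True)
class ImplantedSignal:
    """A (drug, PT) pair whose reporting probability is multiplied by rho.

    ``sex`` optionally restricts the implantation to one reported sex,
    for testing subgroup-specific signal recovery.
    """

    drug: str
    pt: str
    rho: float
    sex: Optional[str] = None

    def __post_init__(self):
        if self.rho <= 0:
            raise ValidationError("implanted multiplier rho must be positive")


@dataclass(frozen=True)
class TargetDrugSpec:
    """Study-drug cohort parameters (Table-1-like reporting structure)."""

    name: str
    synonyms: Tuple[str, ...] = ()
    n_reports: int = 500
    serious_rate: float = 0.13
    missing_age_rate: float = 0.25
    missing_sex_rate: float = 0.08
    events_mean: float = 1.8
    events_dispersion: float = 1.0
    sex_mix: Tuple[float, float, float] = (0.60, 0.30, 0.10)  # F, M, unknown
    age_mix: dict = field(default_factory=lambda: {
        "under18": 0.05, "18_44": 0.50, "45_64": 0.33, "65_plus": 0.12})
    reporter_mix: dict = field(default_factory=lambda: {
        "consumer": 0.45, "physician": 0.20, "pharmacist": 0.10,
        "other_health_professional": 0.15, "not_specified": 0.10})


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration; all randomness flows from ``seed``."""

    seed: int = 0
    n_reports: int = 20_000          # background (non-target) reports
    n_drugs: int = 50                # background drug vocabulary size
    n_pts: int = 250
    n_socs: int = 27
    target_drugs: Tuple[TargetDrugSpec, ...] = ()
    indication_pt: str = "Alopecia areata"
    implanted: Tuple[ImplantedSignal, ...] = ()
    duplicate_rate: float = 0.0      # exact re-submissions (same date)
    followup_rate: float = 0.0       # later-dated follow-up versions
    missing_age_rate: float = 0.25
    missing_sex_rate: float = 0.10
    serious_rate: float = 0.12
    events_mean: float = 1.8
    events_dispersion: float = 1.0
    age_mix: dict = field(default_factory=lambda: {
        "under18": 0.06, "18_44": 0.44, "45_64": 0.33, "65_plus": 0.17})
    date_range: Tuple[str, str] = ("2023-01-01", "2024-03-31")
    onset_present_rate: float = 0.10
    negative_onset_rate: float = 0.02  # of reports with a therapy date
    weight_present_rate: float = 0.10
    orphan_rate: float = 0.0         # REAC rows with unknown primaryid

    def validate(self) -> None:
        rates = {
            "duplicate_rate": self.duplicate_rate,
            "followup_rate": self.followup_rate,
            "missing_age_rate": self.missing_age_rate,
            "missing_sex_rate": self.missing_sex_rate,
            "serious_rate": self.serious_rate,
            "onset_present_rate": self.onset_present_rate,
            "negative_onset_rate": self.negative_onset_rate,
            "weight_present_rate": self.weight_present_rate,
            "orphan_rate": self.orphan_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        target_names = {t.name for t in self.target_drugs}
        for imp in self.implanted:
            if imp.drug not in target_names:
                raise ValidationError(
                    f"implanted signal references unknown drug {imp.drug!r}")


@dataclass
class GroundTruth:
    """What the generator actually did, for exact downstream checks."""

    n_base_reports: int
    n_duplicate_versions: int
    lineage: dict                      # caseid -> ordered primaryid list
    multipliers: dict                  # (drug, pt) -> rho
    target_counts: dict                # drug name -> base report count
    demographics: dict                 # caseid -> (age or None, sex) pre-mask
    implanted: tuple


def make_dictionary(n_pts: int, n_socs: int = 27,
                    seed: int = 0) -> MeddraDict:
    """Deterministic synthetic PT->SOC dictionary.

    SOC names are the 27 real organ-class labels first, synthetic labels
    after; PTs are ``PT_0001``..``PT_<n>`` each assigned exactly one SOC.
    """
    if n_pts < 1 or n_socs < 1:
        raise ValidationError("vocabulary sizes must be positive")
    socs = list(SOC_LABELS[:min(n_socs, len(SOC_LABELS))])
    socs += [f"SOC_{i:02d}" for i in range(len(socs) + 1, n_socs + 1)]
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, n_socs, size=n_pts)
    pt_to_soc = {f"PT_{j + 1:04d}": socs[assignment[j]] for j in range(n_pts)}
    return MeddraDict(pt_to_soc=pt_to_soc,
                      version_label=f"synthetic-{seed}")


def _zipf(n: int, exponent: float, offset: float) -> np.ndarray:
    w = 1.0 / (np.arange(n) + offset) ** exponent
    return w / w.sum()


def _shifted_nb(rng, n, mean, dispersion):
    """Event counts per report: 1 + NegBin with the given excess mean."""
    excess = max(mean - 1.0, 1e-9)
    r = max(dispersion, 1e-6)
    p = r / (r + excess)
    return 1 + rng.negative_binomial(r, p, size=n)


def _pick(rng, options, probs, n):
    probs = np.asarray(probs, dtype=float)
    return rng.choice(len(options), size=n, p=probs / probs.sum())


def _fmt(d: Optional[date]) -> str:
    return d.strftime("%Y%m%d") if d else ""


def _quarter(d: date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def _conditional_pt(p_pt: np.ndarray, pt_index: dict,
                    implants: Sequence[ImplantedSignal]) -> np.ndarray:
    cond = p_pt.copy()
    boosted_mass = 0.0
    for imp in implants:
        j = pt_index[imp.pt]
        boosted_mass += p_pt[j] * imp.rho
        cond[j] = p_pt[j] * imp.rho
    if boosted_mass >= 1.0:
        raise ValidationError(
            "infeasible config: implanted joint mass >= 1 after "
            "multiplication; lower rho or the base PT probabilities")
    return cond / cond.sum()


def generate(config: SynthConfig):
    """Generate quarterly bundles and the matching ground truth.

    Same config and seed give byte-identical files through
    :func:`pvsignal.faers_io.write_bundle`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meddra = make_dictionary(config.n_pts, config.n_socs, config.seed)
    pt_names = sorted(meddra.pt_to_soc)
    pt_index = {pt: j for j, pt in enumerate(pt_names)}
    for imp in config.implanted:
        if imp.pt not in pt_index:
            raise ValidationError(
                f"implanted PT {imp.pt!r} outside the vocabulary")

    p_pt = _zipf(config.n_pts, 1.05, 5.0)
    p_drug = _zipf(config.n_drugs, 1.2, 2.0)
    bg_drugs = [f"DRUG_{i + 1:03d}" for i in range(config.n_drugs)]

    start = date.fromisoformat(config.date_range[0])
    end = date.fromisoformat(config.date_range[1])
    span = (end - start).days
    if span < 0:
        raise ValidationError("date_range end precedes start")

    records = []
    demographics = {}
    target_counts = {}

    def demo_block(n, *, sex_mix, age_mix, missing_age_rate,
                   missing_sex_rate, serious_rate, reporter_mix):
        sex_idx = _pick(rng, ("F", "M", "unknown"), sex_mix, n)
        bands = list(age_mix)
        band_idx = _pick(rng, bands, [age_mix[b] for b in bands], n)
        ages = np.empty(n)
        for k, b in enumerate(bands):
            lo, hi = _AGE_BAND_RANGES[b]
            mask = band_idx == k
            ages[mask] = np.round(rng.uniform(lo, hi, size=mask.sum()), 0)
        age_missing = rng.random(n) < missing_age_rate
        sex_missing = rng.random(n) < missing_sex_rate
        serious = rng.random(n) < serious_rate
        rep_levels = list(reporter_mix)
        rep_idx = _pick(rng, rep_levels, [reporter_mix[r] for r in rep_levels], n)
        country_idx = _pick(rng, _COUNTRIES, _COUNTRY_P, n)
        fda_offsets = rng.integers(0, span + 1, size=n)
        event_lag = rng.integers(0, 61, size=n)
        has_start = rng.random(n) < config.onset_present_rate
        onset = np.round(rng.lognormal(math.log(60.0), 1.2, size=n)).astype(int)
        neg_onset = rng.random(n) < config.negative_onset_rate
        has_wt = rng.random(n) < config.weight_present_rate
        wt = np.round(rng.normal(67.0, 15.0, size=n), 1)
        wt_implausible = rng.random(n) < 0.01
        outc_idx = _pick(rng, _SERIOUS_OUTCOME_CODES, _SERIOUS_OUTCOME_P, n)
        return locals()

    def build_records(n, drug_name, synonyms, cond_by_sex, demo, *,
                      indication, events_mean, events_dispersion):
        ks = _shifted_nb(rng, n, events_mean, events_dispersion)
        name_pool = [drug_name.upper()] + [s.upper() for s in synonyms]
        name_choice = rng.integers(0, len(name_pool), size=n)
        sexes = ("F", "M", "unknown")
        for i in range(n):
            sex = sexes[demo["sex_idx"][i]]
            cond = cond_by_sex.get(sex, cond_by_sex[None])
            ev_idx = rng.choice(config.n_pts, size=ks[i], p=cond)
            fda_dt = start + timedelta(days=int(demo["fda_offsets"][i]))
            event_dt = fda_dt - timedelta(days=int(demo["event_lag"][i]))
            start_dt = None
            if demo["has_start"][i]:
                delta = int(demo["onset"][i])
                if demo["neg_onset"][i]:
                    delta = -max(1, delta // 10)
                start_dt = event_dt - timedelta(days=delta)
            age = float(demo["ages"][i])
            records.append({
                "drug": drug_name,
                "drugname_raw": name_pool[name_choice[i]],
                "true_age": age,
                "age": "" if demo["age_missing"][i] else f"{age:.0f}",
                "sex": "" if demo["sex_missing"][i] else sex,
                "true_sex": sex,
                "serious": bool(demo["serious"][i]),
                "outc": _SERIOUS_OUTCOME_CODES[demo["outc_idx"][i]]
                        if demo["serious"][i] else None,
                "occp": _REPORTER_CODES[
                    list(demo["reporter_mix"])[demo["rep_idx"][i]]],
                "country": _COUNTRIES[demo["country_idx"][i]],
                "fda_dt": fda_dt,
                "event_dt": event_dt,
                "start_dt": start_dt,
                "wt": (f"{(500.0 if demo['wt_implausible'][i] else max(demo['wt'][i], 26.0)):.1f}"
                       if demo["has_wt"][i] else ""),
                "events": [pt_names[j] for j in ev_idx],
                "indication": indication,
            })

    # --- background reports -------------------------------------------------
    n_bg = config.n_reports
    bg_demo = demo_block(
        n_bg, sex_mix=(0.55, 0.35, 0.10), age_mix=config.age_mix,
        missing_age_rate=config.missing_age_rate,
        missing_sex_rate=config.missing_sex_rate,
        serious_rate=config.serious_rate,
        reporter_mix={"consumer": 0.35, "physician": 0.25, "pharmacist": 0.10,
                      "other_health_professional": 0.20,
                      "not_specified": 0.10},
    )
    bg_drug_idx = _pick(rng, bg_drugs, p_drug, n_bg)
    ks = _shifted_nb(rng, n_bg, config.events_mean, config.events_dispersion)
    total_ev = int(ks.sum())
    all_ev = rng.choice(config.n_pts, size=total_ev, p=p_pt)
    splits = np.cumsum(ks)[:-1]
    ev_per_report = np.split(all_ev, splits)
    bg_ind = rng.random(n_bg) < 0.5
    bg_ind_pt = rng.choice(config.n_pts, size=n_bg, p=p_pt)
    sexes = ("F", "M", "unknown")
    for i in range(n_bg):
        fda_dt = start + timedelta(days=int(bg_demo["fda_offsets"][i]))
        event_dt = fda_dt - timedelta(days=int(bg_demo["event_lag"][i]))
        start_dt = None
        if bg_demo["has_start"][i]:
            delta = int(bg_demo["onset"][i])
            if bg_demo["neg_onset"][i]:
                delta = -max(1, delta // 10)
            start_dt = event_dt - timedelta(days=delta)
        age = float(bg_demo["ages"][i])
        records.append({
            "drug": bg_drugs[bg_drug_idx[i]],
            "drugname_raw": bg_drugs[bg_drug_idx[i]],
            "true_age": age,
            "age": "" if bg_demo["age_missing"][i] else f"{age:.0f}",
            "sex": "" if bg_demo["sex_missing"][i] else sexes[bg_demo["sex_idx"][i]],
            "true_sex": sexes[bg_demo["sex_idx"][i]],
            "serious": bool(bg_demo["serious"][i]),
            "outc": _SERIOUS_OUTCOME_CODES[bg_demo["outc_idx"][i]]
                    if bg_demo["serious"][i] else None,
            "occp": _REPORTER_CODES[list(bg_demo["reporter_mix"].keys())[
                bg_demo["rep_idx"][i]]],
            "country": _COUNTRIES[bg_demo["country_idx"][i]],
            "fda_dt": fda_dt,
            "event_dt": event_dt,
            "start_dt": start_dt,
            "wt": (f"{(500.0 if bg_demo['wt_implausible'][i] else max(bg_demo['wt'][i], 26.0)):.1f}"
                   if bg_demo["has_wt"][i] else ""),
            "events": [pt_names[j] for j in ev_per_report[i]],
            "indication": pt_names[bg_ind_pt[i]] if bg_ind[i] else None,
        })

    # --- target-drug reports -----------------------------------------------
    for tspec in config.target_drugs:
        implants = [imp for imp in config.implanted if imp.drug == tspec.name]
        cond_by_sex = {None: _conditional_pt(
            p_pt, pt_index, [i for i in implants if i.sex is None])}
        for sex in ("F", "M", "unknown"):
            sex_implants = [i for i in implants
                            if i.sex is None or i.sex == sex]
            if any(i.sex == sex for i in implants):
                cond_by_sex[sex] = _conditional_pt(p_pt, pt_index, sex_implants)
        demo = demo_block(
            tspec.n_reports, sex_mix=tspec.sex_mix, age_mix=tspec.age_mix,
            missing_age_rate=tspec.missing_age_rate,
            missing_sex_rate=tspec.missing_sex_rate,
            serious_rate=tspec.serious_rate,
            reporter_mix=tspec.reporter_mix,
        )
        build_records(tspec.n_reports, tspec.name, tspec.synonyms,
                      cond_by_sex, demo, indication=config.indication_pt,
                      events_mean=tspec.events_mean,
                      events_dispersion=tspec.events_dispersion)
        target_counts[tspec.name] = tspec.n_reports

    # --- ids, duplicate/follow-up versions ----------------------------------
    n_base = len(records)
    lineage = {}
    for i, rec in enumerate(records):
        rec["primaryid"] = str(100_000_001 + i)
        rec["caseid"] = str(200_000_001 + i)
        lineage[rec["caseid"]] = [rec["primaryid"]]
        demographics[rec["caseid"]] = (rec["true_age"], rec["true_sex"])

    versions = []
    dup_mask = rng.random(n_base) < config.duplicate_rate
    fup_mask = rng.random(n_base) < config.followup_rate
    fup_delay = rng.integers(1, 91, size=n_base)
    next_id = 100_000_001 + n_base
    for i, rec in enumerate(records):
        if dup_mask[i]:
            v = dict(rec)
            v["primaryid"] = str(next_id)
            next_id += 1
            versions.append(v)
            lineage[rec["caseid"]].append(v["primaryid"])
        if fup_mask[i]:
            v = dict(rec)
            v["primaryid"] = str(next_id)
            next_id += 1
            v["fda_dt"] = rec["fda_dt"] + timedelta(days=int(fup_delay[i]))
            versions.append(v)
            lineage[rec["caseid"]].append(v["primaryid"])
    all_records = records + versions

    # --- emit quarterly bundles ---------------------------------------------
    bundles: dict = {}

    def bundle_for(d: date) -> QuarterBundle:
        label = _quarter(d)
        if label not in bundles:
            bundles[label] = QuarterBundle(label)
        return bundles[label]

    for rec in all_records:
        b = bundle_for(rec["fda_dt"])
        pid, cid = rec["primaryid"], rec["caseid"]
        b.rows("DEMO").append(RawTableRow("DEMO", {
            "primaryid": pid, "caseid": cid,
            "fda_dt": _fmt(rec["fda_dt"]), "event_dt": _fmt(rec["event_dt"]),
            "age": rec["age"], "age_cod": "YR" if rec["age"] else "",
            "sex": rec["sex"], "wt": rec["wt"],
            "wt_cod": "KG" if rec["wt"] else "",
            "occp_cod": rec["occp"], "occr_country": rec["country"],
            "reporter_country": rec["country"],
            "serious": "Y" if rec["serious"] else "N",
        }))
        b.rows("DRUG").append(RawTableRow("DRUG", {
            "primaryid": pid, "caseid": cid, "drug_seq": "1",
            "role_cod": "PS", "drugname": rec["drugname_raw"],
        }))
        for pt in rec["events"]:
            b.rows("REAC").append(RawTableRow("REAC", {
                "primaryid": pid, "caseid": cid, "pt": pt,
            }))
        if rec["outc"]:
            b.rows("OUTC").append(RawTableRow("OUTC", {
                "primaryid": pid, "caseid": cid, "outc_cod": rec["outc"],
            }))
        if rec["start_dt"]:
            b.rows("THER").append(RawTableRow("THER", {
                "primaryid": pid, "caseid": cid, "dsg_drug_seq": "1",
                "start_dt": _fmt(rec["start_dt"]),
            }))
        if rec["indication"]:
            b.rows("INDI").append(RawTableRow("INDI", {
                "primaryid": pid, "caseid": cid, "indi_drug_seq": "1",
                "indi_pt": rec["indication"],
            }))
        b.rows("RPSR").append(RawTableRow("RPSR", {
            "primaryid": pid, "caseid": cid,
            "rpsr_cod": "HP" if rec["occp"] in ("MD", "PH", "OT") else "CSM",
        }))

    if config.orphan_rate > 0:
        n_orphans = int(round(config.orphan_rate * n_base))
        orphan_pts = rng.choice(config.n_pts, size=n_orphans, p=p_pt)
        first = bundles[sorted(bundles)[0]]
        for j in range(n_orphans):
            first.rows("REAC").append(RawTableRow("REAC", {
                "primaryid": str(900_000_001 + j), "caseid": str(900_000_001 + j),
                "pt": pt_names[orphan_pts[j]],
            }))

    truth = GroundTruth(
        n_base_reports=n_base,
        n_duplicate_versions=len(versions),
        lineage=lineage,
        multipliers={(i.drug, i.pt): i.rho for i in config.implanted},
        target_counts=target_counts,
        demographics=demographics,
        implanted=tuple(config.implanted),
    )
    ordered = [bundles[label] for label in sorted(bundles)]
    return ordered, truth


def scenario_jak_alopecia(seed: int = 0) -> SynthConfig:
    """Two-target-drug scenario shaped like the published cohort tables.

    Drug one (baricitinib-like): 550 reports, ~60/25/15 sex mix, ~50%
    missing age, ~15% serious, ~1.7 events per report. Drug two
    (tofacitinib-like): 648 reports, ~10% missing age, ~11% serious, ~3.0
    events per report. Background: 10,000 reports over 50 drugs.
    """
    bari = TargetDrugSpec(
        name="baricitinib", synonyms=("olumiant",), n_reports=550,
        serious_rate=0.15, missing_age_rate=0.50, missing_sex_rate=0.15,
        events_mean=1.7, sex_mix=(0.60, 0.25, 0.15),
        age_mix={"under18": 0.03, "18_44": 0.55, "45_64": 0.33,
                 "65_plus": 0.09},
        reporter_mix={"consumer": 0.70, "not_specified": 0.17,
                      "pharmacist": 0.09, "physician": 0.04,
                      "other_health_professional": 0.00},
    )
    tofa = TargetDrugSpec(
        name="tofacitinib", synonyms=("xeljanz", "xeljanz xr"), n_reports=648,
        serious_rate=0.11, missing_age_rate=0.10, missing_sex_rate=0.05,
        events_mean=3.0, sex_mix=(0.63, 0.32, 0.05),
        age_mix={"under18": 0.24, "18_44": 0.44, "45_64": 0.25,
                 "65_plus": 0.07},
        reporter_mix={"other_health_professional": 0.47, "consumer": 0.26,
                      "physician": 0.18, "pharmacist": 0.08,
                      "not_specified": 0.01},
    )
    return SynthConfig(
        seed=seed, n_reports=10_000, n_drugs=50, n_pts=250, n_socs=27,
        target_drugs=(bari, tofa), duplicate_rate=0.03, followup_rate=0.04,
    )


def scenario_signal_recovery(seed: int = 0, n_reports: int = 50_000,
                             n_implanted: int = 5,
                             rho: float = 8.0) -> SynthConfig:
    """One target drug with implanted signal PTs against a large background.

    Implanted PTs are taken from mid-rank background terms (ranks 40, 45,
    ... in the Zipf marginal) so that at rho = 8 the expected cohort count
    per implanted PT is around 20 — large enough to be detectable, small
    enough that shrinkage matters.
    """
    pts = [f"PT_{40 + 5 * i:04d}" for i in range(n_implanted)]
    target = TargetDrugSpec(
        name="baricitinib", synonyms=("olumiant",), n_reports=500,
        events_mean=1.8,
    )
    implants = tuple(ImplantedSignal("baricitinib", pt, rho) for pt in pts)
    return SynthConfig(
        seed=seed, n_reports=n_reports, n_drugs=50, n_pts=250, n_socs=27,
        target_drugs=(target,), implanted=implants,
        duplicate_rate=0.03, followup_rate=0.03,
    )
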