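"""Whole-cohort and subgroup disproportionality screens."""

import random

import numpy as np
import pandas as pd
import pytest

from pvsignal.cleaning import SynonymMap, clean_cases
from pvsignal.cohort import select_cohort
from pvsignal.errors import ValidationError
from pvsignal.faers_io import assemble_cases
from pvsignal.records import DrugEntry, MeddraDict, ReportCase
from pvsignal.screen import (SubgroupSpec, build_contingency, heatmap_matrix,
                             rank_top, run_screen, screen_to_frame,
                             subgroup_screen)
from pvsignal.synthetic import (ImplantedSignal, SynthConfig, TargetDrugSpec,
                                generate, make_dictionary)

AA = {"Alopecia areata"}


def report(pid, events, drug="drugX", sex="F", age=30.0):
    return ReportCase(
        primaryid=pid, caseid=pid, sex=sex, age_years=age,
        drugs=[DrugEntry(drug, "PS", indication_pt="Alopecia areata",
                         name_canonical=drug)],
        events=list(events),
    )


@pytest.fixture(scope="module")
def small_world():
    cohort = [report(f"c{i}", ["PT_X"]) for i in range(10)]
    rest = ([report(f"b{i}", ["PT_X"], drug="other") for i in range(20)]
            + [report(f"n{i}", ["PT_Y"], drug="other") for i in range(970)])
    return cohort, cohort + rest


class TestBuildContingency:
    def test_definition(self, small_world):
        cohort, background = small_world
        t = build_contingency(cohort, background, "PT_X")
        assert (t.a, t.b, t.c, t.d) == (10, 0, 20, 970)

    def test_absent_pt(self, small_world):
        cohort, background = small_world
        t = build_contingency(cohort, background, "PT_Z")
        assert t.a == 0 and t.c == 0

    def test_repeat_pts_count_once_per_report(self):
        cohort = [report("c1", ["PT_X", "PT_X"])]
        background = cohort + [report("b1", ["PT_Y"])]
        assert build_contingency(cohort, background, "PT_X").a == 1

    def test_cohort_must_be_subset(self, small_world):
        cohort, background = small_world
        with pytest.raises(ValidationError, match="subset"):
            build_contingency(cohort, background[10:], "PT_X")


class TestRunScreen:
    DICT = MeddraDict({f"PT_{c}": "General disorders and administration "
                                  "site conditions" for c in "XYZ"})

    def test_empty_cohort(self, small_world):
        _, background = small_world
        res = run_screen([], background, self.DICT)
        assert len(res) == 0 and res.cohort_size == 0

    def test_invariant_to_input_order(self, small_world):
        cohort, background = small_world
        res1 = run_screen(cohort, background, self.DICT, min_a=1)
        rng = random.Random(3)
        cohort2, background2 = cohort[:], background[:]
        rng.shuffle(cohort2)
        rng.shuffle(background2)
        res2 = run_screen(cohort2, background2, self.DICT, min_a=1)
        pd.testing.assert_frame_equal(screen_to_frame(res1),
                                      screen_to_frame(res2))

    def test_min_a_gate(self, small_world):
        cohort, background = small_world
        cohort = cohort + [report("cz", ["PT_Z"])]
        background = background + [cohort[-1]]
        res = run_screen(cohort, background, self.DICT, min_a=3)
        assert [r.pt for r in res.rows] == ["PT_X"]
        res1 = run_screen(cohort, background, self.DICT, min_a=1)
        assert {r.pt for r in res1.rows} == {"PT_X", "PT_Z"}


class TestRankTop:
    def make_result(self, jak_dataset):
        cases = jak_dataset["cases"]
        cohort = select_cohort(cases, "tofacitinib", AA, adult_only=True)
        return run_screen(cohort, cases, jak_dataset["meddra"])

    def test_top_30_of_a_large_screen(self, jak_dataset):
        res = self.make_result(jak_dataset)
        assert len(res.rows) > 30
        top = rank_top(res, 30, key="frequency")
        assert len(top) == 30
        counts = [r.table.a for r in top]
        assert counts == sorted(counts, reverse=True)

    def test_k_capped_at_row_count(self, jak_dataset):
        res = self.make_result(jak_dataset)
        assert len(rank_top(res, 10_000)) == len(res.rows)

    def test_ties_break_alphabetically(self, small_world):
        cohort = [report("c1", ["PT_B", "PT_A"]), report("c2", ["PT_A", "PT_B"]),
                  report("c3", ["PT_A", "PT_B"])]
        background = cohort + [report(f"b{i}", ["PT_C"]) for i in range(100)]
        d = MeddraDict({p: "Investigations" for p in ("PT_A", "PT_B", "PT_C")})
        res = run_screen(cohort, background, d)
        assert [r.pt for r in rank_top(res, 2)] == ["PT_A", "PT_B"]

    def test_strength_and_signal_count_keys(self, jak_dataset):
        res = self.make_result(jak_dataset)
        strength = rank_top(res, 5, key="strength")
        ebgms = [r.metrics.ebgm for r in strength]
        assert ebgms == sorted(ebgms, reverse=True)
        with pytest.raises(ValidationError):
            rank_top(res, 5, key="nope")


class TestSubgroups:
    def test_per_level_counts_partition_whole_cohort(self, jak_dataset):
        cases = jak_dataset["cases"]
        meddra = jak_dataset["meddra"]
        cohort = select_cohort(cases, "baricitinib", AA, adult_only=True)
        whole = run_screen(cohort, cases, meddra, min_a=1)
        sub = subgroup_screen(cohort, cases, SubgroupSpec("gender"), meddra,
                              min_a=1, min_cohort=0)
        whole_a = {r.pt: r.table.a for r in whole.rows}
        summed = {}
        for res in sub.values():
            for r in res.rows:
                summed[r.pt] = summed.get(r.pt, 0) + r.table.a
        assert summed == whole_a

    def test_small_stratum_skipped(self, small_world):
        cohort, background = small_world  # all cohort cases are female
        d = MeddraDict({p: "Investigations" for p in ("PT_X", "PT_Y")})
        sub = subgroup_screen(cohort, background, SubgroupSpec("gender"), d,
                              min_cohort=5)
        assert not sub["F"].skipped
        assert sub["M"].skipped and len(sub["M"].rows) == 0

    def test_sex_restricted_implant_flagged_only_in_that_stratum(self):
        """A female-only implanted pair signals in the F screen, not in M."""
        hits = 0
        for seed in (0, 1):
            cfg = SynthConfig(
                seed=seed, n_reports=20_000, n_pts=250,
                target_drugs=(TargetDrugSpec(name="baricitinib",
                                             n_reports=600,
                                             missing_sex_rate=0.0),),
                implanted=(ImplantedSignal("baricitinib", "PT_0040", 10.0,
                                           sex="F"),),
            )
            bundles, _ = generate(cfg)
            cases, _ = clean_cases(assemble_cases(bundles).cases)
            meddra = make_dictionary(cfg.n_pts, cfg.n_socs, cfg.seed)
            cohort = select_cohort(cases, "BARICITINIB".casefold(), AA)
            sub = subgroup_screen(cohort, cases, SubgroupSpec("gender"),
                                  meddra, min_a=1, min_cohort=0)
            f_flags = {r.pt: r.metrics.flags["ror"] for r in sub["F"].rows}
            m_flags = {r.pt: r.metrics.flags["ror"] for r in sub["M"].rows}
            if f_flags.get("PT_0040") and not m_flags.get("PT_0040", False):
                hits += 1
        assert hits == 2

    def test_within_indication_comparator_is_null_on_split_cohort(
            self, jak_dataset):
        """Half a cohort screened against the full cohort is a true null:
        both halves share the same event distribution, so ROR CIs should
        span 1 at roughly nominal frequency."""
        cases = jak_dataset["cases"]
        meddra = jak_dataset["meddra"]
        full = select_cohort(cases, "baricitinib", AA)
        half = full[::2]
        res = run_screen(half, full, meddra, min_a=3,
                         comparator_mode="within_indication")
        rors = np.array([r.metrics.ror for r in res.rows])
        covered = np.mean([r.metrics.ror_lo95 <= 1 <= r.metrics.ror_hi95
                           for r in res.rows])
        assert 0.3 < np.median(rors) < 3.0
        assert covered > 0.85


class TestHeatmap:
    def test_single_level_equals_its_top_k(self, jak_dataset):
        cases = jak_dataset["cases"]
        cohort = select_cohort(cases, "baricitinib", AA, adult_only=True)
        res = run_screen(cohort, cases, jak_dataset["meddra"])
        metric_df, count_df = heatmap_matrix({"all": res}, top_k=10)
        top = {r.pt for r in rank_top(res, 10, key="frequency")}
        assert set(metric_df.index) == top
        assert metric_df.shape[1] == 1
        assert count_df.loc[:, "all"].notna().all()

    def test_missing_marker_for_pt_absent_from_a_level(self, small_world):
        d = MeddraDict({p: "Investigations" for p in ("PT_A", "PT_B", "PT_C")})
        cohort_f = [report(f"f{i}", ["PT_A"], sex="F") for i in range(5)]
        cohort_m = [report(f"m{i}", ["PT_B"], sex="M") for i in range(5)]
        cohort = cohort_f + cohort_m
        background = cohort + [report(f"x{i}", ["PT_C"], sex=("F", "M")[i % 2])
                               for i in range(200)]
        sub = subgroup_screen(cohort, background, SubgroupSpec("gender"), d,
                              min_a=1, min_cohort=1)
        metric_df, _ = heatmap_matrix(sub, top_k=5)
        assert np.isnan(metric_df.loc["PT_A", "M"])
        assert np.isnan(metric_df.loc["PT_B", "F"])
        assert not np.isnan(metric_df.loc["PT_A", "F"])

    def test_labels_roundtrip_through_writer(self, tmp_path, small_world):
        cohort, background = small_world
        d = MeddraDict({p: "Investigations" for p in ("PT_X", "PT_Y")})
        sub = subgroup_screen(cohort, background, SubgroupSpec("gender"), d,
                              min_cohort=1)
        metric_df, _ = heatmap_matrix(sub, top_k=5)
        path = tmp_path / "hm.tsv"
        metric_df.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert list(back.index) == list(metric_df.index)
        assert list(back.columns) == list(metric_df.columns)
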