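"""Stratified screens and the PT-by-subgroup heatmap matrix.

Implants one female-only signal, screens the cohort separately per sex
stratum (background restricted to the same stratum), and prints the
information-component matrix that a heatmap figure would color.
"""

from pvsignal import (SubgroupSpec, assemble_cases, clean_cases, generate,
                      heatmap_matrix, make_dictionary, select_cohort,
                      subgroup_screen)
from pvsignal.cleaning import SynonymMap
from pvsignal.synthetic import ImplantedSignal, SynthConfig, TargetDrugSpec

config = SynthConfig(
    seed=0, n_reports=20_000,
    target_drugs=(TargetDrugSpec(name="baricitinib", n_reports=600,
                                 missing_sex_rate=0.0),),
    implanted=(ImplantedSignal("baricitinib", "PT_0040", 10.0, sex="F"),),
)
bundles, _ = generate(config)
maps = [SynonymMap.build(t.name, t.synonyms) for t in config.target_drugs]
cases, _ = clean_cases(assemble_cases(bundles).cases, synonym_maps=maps)
meddra = make_dictionary(config.n_pts, config.n_socs, config.seed)

cohort = select_cohort(cases, "baricitinib", {"Alopecia areata"})
results = subgroup_screen(cohort, cases, SubgroupSpec("gender"), meddra)
metric_df, count_df = heatmap_matrix(results, top_k=8)

print("information component (IC) by sex stratum; NaN = PT not screened "
      "in that stratum:\n")
print(metric_df.round(2))
print("\nPT_0040 carries a female-only implanted signal: its IC should be "
      "clearly positive in the F column while the M column shows no "
      "elevation (NaN when the term is too rare there to screen).")
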