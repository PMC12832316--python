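"""Generate a synthetic FAERS-style quarterly dataset with known truth.

Builds the two-study-drug scenario (550 and 648 target reports over a
10,000-report background), writes the quarterly ASCII bundles plus the
PT->SOC dictionary, and prints what was implanted.
"""

from pathlib import Path

from pvsignal import generate, make_dictionary, scenario_jak_alopecia
from pvsignal import write_bundle, write_meddra_dict

out = Path("scratch/example_data")
config = scenario_jak_alopecia(seed=0)
bundles, truth = generate(config)

out.mkdir(parents=True, exist_ok=True)
for bundle in bundles:
    write_bundle(bundle, out)
write_meddra_dict(make_dictionary(config.n_pts, config.n_socs, config.seed),
                  out / "meddra.tsv")

print(f"quarters written : {[b.quarter_label for b in bundles]}")
print(f"base reports     : {truth.n_base_reports}")
print(f"duplicate versions: {truth.n_duplicate_versions} "
      "(extra submissions sharing a caseid; deduplication must remove "
      "exactly these)")
print(f"target cohorts   : {truth.target_counts}")
# The target cohort sizes are ground truth: after cleaning, selecting each
# drug with the alopecia-areata indication must recover exactly these counts.
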