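# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the places where the design was genuinely open.

## Scope and model of the data

The unit of observation is a *spontaneous safety report*: one submission
describing one patient, one or more drugs (each with a role code and
optionally an indication), and one or more adverse events coded as
preferred terms (PTs), each PT belonging to exactly one system organ
class (SOC). Reports accumulate *versions*: a case (caseid) may be
re-submitted or followed up under new primaryids. Because reporting is
voluntary and exposure denominators do not exist, all quantities computed
here describe *reporting*, not risk; a flagged pair is a
hypothesis-generating signal, never a causal claim.

## Cleaning

**Deduplication** keeps exactly one version per caseid: the one with the
latest report date, ties broken by the numerically (else lexically)
greatest primaryid. This operationalizes the usual "retain the most
recent version" rule, which does not by itself specify tie-breaks; making
the tie-break explicit makes the operation deterministic, idempotent and
order-invariant, and those three properties are tested directly.
Follow-up "merging" is realized as selection of the retained version, not
field-level union: a field-level merge has no auditable specification,
and selection keeps every retained value traceable to one submission.

**Implausible values** are recoded to missing, never imputed: negative
onset intervals (event before therapy start), ages outside [0, 120]
years, weights outside [2, 400] kg. The bounds are configurable; the
defaults are conventional plausibility cut-offs.

**Drug-name standardization** is exact match (after trimming and case
folding) against user-supplied synonym maps. Fuzzy matching is
deliberately excluded: a wrong fuzzy hit silently moves a report between
cohorts, and case selection must stay auditable.

**Completeness filtering** (dropping reports missing age, sex or onset)
exists as a switch but defaults to OFF. Real spontaneous cohorts carry
very large not-specified fractions (half the reports for a recently
approved drug is unremarkable), and published cohort tables routinely
tabulate those reports rather than drop them; a hard filter would make
the descriptive stage unrepresentative.

## Cohorts and events

A report enters a drug cohort when some drug entry simultaneously has the
canonical drug name, a suspect role (primary or secondary), and an
indication PT from the study set *attached to that entry*. Tying the
indication to the suspect-drug entry (rather than accepting any
indication anywhere on the report) prevents cohort contamination by
concomitant therapy. The adult filter (age ≥ 18) applies only to signal
cohorts and retains missing ages; descriptive tables run over all ages so
that the age distribution itself, including the pediatric and
not-specified rows, remains visible.

Event-level records are (report, distinct PT) pairs: a PT repeated within
one report (a common artifact of follow-up consolidation) counts once.
All screening counts are report-level for the same reason.

## Descriptive statistics

Percents are rounded half-up to two decimals against the stated
denominator (report or event totals), matching print conventions.
Quartiles use linear interpolation between order statistics. Categorical
comparisons use Pearson's chi-square without continuity correction by
default (Yates by flag — the headline seriousness comparison is
significant either way); when any expected cell is below five the 2×2
Fisher exact test is used, with the two-sided p defined as the sum of
probabilities of tables no more probable than the observed one. The
Mann–Whitney U test is exact (full label-permutation enumeration with
midranks, two-sided p = P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|)) when the
smaller sample has at most eight observations and the enumeration stays
under 2·10⁵ combinations; otherwise the tie-corrected normal
approximation. The exact definition is symmetric under group swap and
handles ties, and reduces to classical tail doubling without ties. No
multiplicity adjustment is applied to descriptive comparisons — none is
conventional for this table style — and outputs should be read
accordingly.

Seriousness is tracked two ways at once: the source record's seriousness
flag and the outcome-code set (death, life-threatening, hospitalization,
disability, congenital anomaly, required intervention). A report is
serious if either says so. The two need not reconcile in real data, which
is why both are kept.

## Disproportionality estimators

For each screened PT the 2×2 table is a (cohort with event), b (cohort
without), c (comparator with), d (comparator without); N = a+b+c+d and
E = (a+b)(a+c)/N.

* **ROR** = ad/bc with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  If any cell is zero, 0.5 is added to *all* cells (estimate and CI).
* **PRR** = [a/(a+b)]/[c/(c+d)]; its companion chi-square is the
  Yates-corrected Pearson statistic on the raw cells (correction
  configurable off). With a = 0 the PRR is reported as 0 and no
  continuity correction is applied to the ratio.
* **BCPNN IC** = log₂((a+0.5)/(E+0.5)) with the closed-form credibility
  bounds IC025 = IC − 3.3(a+0.5)^(−1/2) − 2.0(a+0.5)^(−3/2) and
  IC975 = IC + 2.4(a+0.5)^(−1/2) − 0.5(a+0.5)^(−3/2). The closed form is
  the de-facto convention in FAERS screening; the original full-Bayes
  network formulation and MCMC variants are out of scope.
* **MGPS**: the Poisson rate ratio λ has a two-component gamma mixture
  prior with five hyperparameters (α₁, β₁, α₂, β₂, w). The marginal of a
  given E is a mixture of negative binomials; the hyperparameters are
  fitted once per screen by maximizing the summed marginal log-likelihood
  over all cells with a ≥ 1, by bounded L-BFGS-B from the fixed start
  (0.2, 0.1, 2.0, 4.0, 1/3) with box bounds [10⁻⁵, 20] on shapes/rates
  and [10⁻³, 1−10⁻³] on the weight. No stratification of E and no data
  squashing is applied. The posterior is
  Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a, β₂+E) with Q the posterior
  component weight; EBGM = exp(E[ln λ]) via the digamma function, and
  EB05 is the posterior 5th percentile obtained by Brent root-finding on
  the mixture CDF (xtol 10⁻¹², bracket grown from the component 99.9%
  quantiles).

Signal thresholds default to the conventional rules (ROR: a ≥ 3 and CI
lower bound > 1; PRR: a ≥ 3, PRR ≥ 2, χ² ≥ 4; BCPNN: IC025 > 0; MGPS:
EB05 > 2) and are configuration, printed into every output. Boundary
comparisons are strict where the rule says "greater than".

Numerical notes: IC and EBGM are exact closed forms; the only iterative
pieces are the prior fit (deterministic given data and start — the
optimizer is monotone from the fixed start, and the fitted likelihood is
asserted against the start in tests) and the EB05 root find, which is
cross-checked against quadrature-plus-bisection inversion of the
posterior CDF to 10⁻⁶ in the test suite. Degenerate inputs: an all-zero
count vector still fits (the prior collapses toward a small mean); an
empty table (N = 0) is rejected.

## Screens and subgroups

The default comparator is the full cleaned database minus the cohort
("full database" mode), the dominant convention in FAERS studies; a
within-indication comparator is available because published analyses are
often ambiguous on this point. Rows are screened at a ≥ 3 by default (the
same gate the ROR/PRR rules impose) while the prior fit uses all a ≥ 1
cells for stability. Rankings (frequency, signal count, strength) break
ties alphabetically by PT so output order is stable. Subgroup screens
restrict cohort *and* comparator to the stratum — otherwise demographic
reporting imbalances masquerade as drug signals — and strata with fewer
than 10 cohort reports are emitted as skipped rather than fitted on
noise. Heatmap matrices take the union of each stratum's top-k PTs by
report count and default to the IC as the colored metric, with the count
matrix alongside; absent cells are missing markers, not zeros.

## The synthetic generator

The generator's defaults define the study conditions the tests run
under. Background reports draw a drug from a Zipf-like marginal over 50
synthetic drugs and events from a Zipf-like marginal over 250 PTs (the
joint is the product, i.e., independence). Implanted pairs multiply the
joint probability of a (target drug, PT) pair by ρ and renormalize, so ρ
is interpretable as a relative reporting ratio; configurations whose
implanted mass reaches 1 are rejected. Events per report are shifted
negative binomial (minimum one reaction). Duplicates (same date, new
primaryid) and follow-ups (1–90 days later) share the caseid, and the
emitted lineage exactly predicts the deduplication count. The PT→SOC
dictionary assigns synthetic PT names to the 27 real SOC labels. Dates
are uniform over six quarters; report versions land in quarter bundles by
report date.

Two canned scenarios fix the conditions used throughout testing:

* **JAK-alopecia** (`scenario_jak_alopecia`): two target drugs shaped like a published two-cohort
  table — 550 reports (≈60/25/15 sex mix, ~50% missing age, ~15%
  serious, ~1.7 events/report) vs 648 reports (~10% missing age, ~11%
  serious, ~3.0 events/report) over a 10,000-report background.
* **signal recovery**: one 500-report target cohort over a 50,000-report
  background with five implanted PTs at ρ = 8, chosen from mid-rank
  terms so the expected cohort count per implanted PT is ≈20.

What the generator does *not* emulate: misspelled drug-name
distributions, narrative text, correlated event co-reporting within a
report beyond the shared drug conditional, reporting-rate drift over
time, and country-specific reporting cultures. Passing tests therefore
demonstrate that the pipeline recovers known structure from
schema-faithful data; they do not certify performance on the full
messiness of real archives.

## Problem sizes

The test suite and the acceptance script use: 1,000 random tables for
estimator-oracle agreement; 1,000 fixed-margin replicates (N = 10,000,
margins 1,000 × 200, E = 20) for null calibration; ten seeds of the
signal-recovery scenario (50,000 background reports each, one seed run
through a full file write/read round trip); and the JAK-alopecia scenario
for descriptive and subgroup checks. These sizes make the binomial bands
in the assertions meaningful while keeping a full run in the low minutes
on one CPU.

## Known limitations

Exact-match standardization means unmapped name variants leave reports
out of cohorts (they are marked, not guessed). The Fisher path is 2×2
only; sparse larger tables must be collapsed by the caller. The MGPS
implementation is the pairwise shrinker; multi-item (interaction) terms
and stratified expected counts are not implemented. Time-scan methods
(quarter-by-quarter signal emergence) are out of scope.
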