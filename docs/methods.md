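# Methods

## Problem setting

Spontaneous adverse-event databases such as FAERS collect voluntary reports,
each carrying one or more suspected drugs, one or more MedDRA preferred-term
(PT) event codes, demographics and seriousness outcomes. There is no
denominator of drug exposure, so absolute risks cannot be estimated; instead,
disproportionality analysis asks whether a PT's share of the target drug's
reports exceeds its share of all other reports. `vigilstat` implements this
for a target *combination* of drugs (the motivating use case is a
statin–fibrate pair), where a report is "exposed" when every target drug
appears on it with the primary-suspect role.

## Report handling

**Deduplication.** FAERS re-submits amended cases under the same case id
with a new version number. We keep, per case id, the record with the highest
version, breaking version ties by the latest receipt date and then by last
occurrence in input order. This mirrors the database's own case-version
convention; content-similarity duplicate detection is out of scope.

**Inclusion.** The exposed cohort requires each target drug to carry the
primary-suspect (PS) role on the same report. This is the strictest reading
of "first suspect drugs"; a flag (`allow_secondary=True`) relaxes it to any
suspect role (PS or SS), since reporting practice varies. Drug-name matching
is exact after case-folding and whitespace normalisation; salt/brand
resolution is left to the user's pre-mapping.

**Exclusion.** Event terms that restate the treated condition (drug
indications, concomitant disease) are not adverse events. They are removed
from each report's reaction set using a user-supplied PT list; a report left
with no reactions is dropped. No built-in list ships with the package
because the appropriate terms depend on the indication under study.

## Counting and the 2×2 table

The counting unit is a distinct (report, PT) pair: a report listing k PTs
contributes k pairs to its cohort margin. Under this convention, for a given
PT, a = exposed pairs with the PT, b = all other exposed pairs, c and d the
same in the background, and the per-PT counts a sum exactly to the exposed
pair total. Report-level counting (each report once per cell) is available
via `counting="reports"`; it changes b and d but not a and c. Analysis is
restricted to the `n_top` most-reported PTs (default 250), ranked by a
descending with alphabetical tie-break for platform-independent
determinism.

## Statistics

PRR and ROR use log-scale Wald 95% intervals — the de-facto convention in
pharmacovigilance. No continuity correction is applied: PRR is undefined when a = 0 or c = 0,
ROR when any cell is 0, and an undefined statistic never passes its
criterion. Since the signal
criterion already requires a ≥ 3, zero-a tables are moot.

The BCPNN information component uses the classical closed-form posterior
moments with prior constants α₁ = β₁ = γ₁₁ = 1, α = β = 2, and the joint
prior scale γ tied to the margins so that E[IC] = 0 under prior
independence. E[IC] is the log₂ of the ratio of posterior means (the
standard published form), not the posterior mean of the log — the two agree
to O(1/a); the test suite checks the closed form against both a 50-digit
re-evaluation (mpmath) and a 10⁶-draw Monte-Carlo sample from the Beta
posteriors, the latter on tables large enough (a ≥ 40) that the
delta-method gap stays below 0.02 bits. All three V[IC] summands have the
symmetric form (C − margin + prior-total − prior-component); the variance is
expressed in bits².

**Joint criterion.** A term is a signal when all three methods pass
(a ≥ 3, PRR and ROR lower CI bound > 1, IC−2SD > 0). Conjunction was chosen
as the default because it is the conservative reading of "signals detected
by PRR, ROR and BCPNN"; disjunction is one keyword away
(`criteria="disjunction"`). No multiple-testing adjustment is applied — the
disproportionality thresholds are the only gate, as is standard for this
screen.

## Gender-stratified ROR

Within the exposed cohort only, for each of the k most-reported PTs
(default 10), the female-vs-male odds ratio (a_f·b_m)/(b_f·a_m) is computed
report-wise with the same Wald interval. Unknown-sex reports are excluded
from all four cells but still count toward the PT ranking, so the "reports"
column matches the overall most-frequent list. OR > 1 means the event is
reported relatively more often for women. Any zero cell yields an undefined
result rather than an infinite or corrected estimate.

## Summaries

Demographic blocks (sex; age bands <18, 18–44, 45–64, 65–74, ≥75, unknown
with inclusive lower edges; six reporter-occupation classes) and a
seriousness block share the cohort size as denominator. A report with
several serious outcomes is counted once under the most severe
(death > life-threatening > hospitalization > disabling > congenital
anomaly — the conventional severity order; configurable in code). A derived
"Serious total" row counts reports with at least one serious outcome.
Percentages are rounded half-up to two decimals, reproducing published
tables of this kind exactly. SOC rollups sum per-PT a counts over a
user-supplied PT→SOC TSV (MedDRA is licensed and not redistributed);
unmapped PTs group under "Unmapped" and counts are conserved under any
partition. Label annotation flags each signal PT against a user-supplied,
case-normalised label-term list.

## Synthetic corpus generator

The generator draws, per report: exposure to the target combination
(Bernoulli, default probability 0.1); a suspect-drug list (exposed reports
carry the combination as primary suspects; background reports sample from a
small catalog of common co-medications and never carry the full combination
as primary suspects, so the suspect filter recovers the exposed set
exactly); a reaction set with each PT included independently with
probability p_background·RR (capped at 1, cap events logged), redrawn until
non-empty; sex, age band (age uniform within band), occupation and at most
one serious outcome from categorical distributions; and optionally a
duplicated fraction of reports re-emitted with incremented case versions.
The redraw makes the per-PT inclusion probability conditional on a
non-empty report exactly p_j/(1 − Π(1 − p_k)), and `expected_two_by_two`
uses that closed form, so realized tables can be compared to expectations
without simulation bias.

Defaults encode a realistic cohort for this drug class: a slight male
majority (54.5/41.4/4.1% M/F/unknown), middle-aged-and-older ages with ~39%
unknown, consumers as the largest reporter class, ~43% serious reports
dominated by hospitalization, and a 200-term PT catalog whose background
probabilities span two orders of magnitude and sum to 3 expected reactions
per report. The study-condition factories fix the validation designs:
`independence_config` (2,000 reports, 200 PTs, all RR = 1) for null
calibration, and `signal_config` (same size, one injected association with
RR = 10 and background probability 0.01, i.e. expected exposed count 20)
for recovery. A `female_rr` map multiplies chosen PTs' inclusion
probabilities for female patients, providing ground truth for the
sex-stratified ROR.

What the generator does **not** emulate: correlation between PTs within a
report, drug–drug interaction structure, covariate-dependent reporting
(other than the optional sex effect), secular time trends, and free-text
irregularities. Passing tests therefore demonstrate correctness of the
counting and statistics under the model the methods assume, not robustness
to real FAERS messiness (name variants, partial duplicates, indication
noise), which the filtering operations only partially address.

## Numerical choices and edge cases

* Wald z is 1.959963984540054 (the exact two-sided 95% normal quantile).
* Undefined ratios are NaN triples, never exceptions, and never pass
  criteria; degenerate margins (a+b = 0 or c+d = 0) in PRR raise, since the
  table itself is malformed.
* Percent rounding is decimal half-up, not banker's rounding.
* Top-N and output files are deterministically ordered (count descending,
  then PT; rows by case id), so repeated runs are byte-identical.
* Problem sizes in the validation studies (2,000 reports × 200 PTs × 50
  replicates) were chosen as the smallest designs at which the expected
  signal count (a ≈ 20) sits well inside the detectable regime while null
  calibration is still estimated from ~10⁴ PT-level tests.

## Known limitations

Disproportionality measures reporting, not incidence; confounding by
indication, stimulated reporting and duplicate submissions can all produce
or mask signals. The analysis ignores time-to-onset and any within-report
PT correlation. The exposed/background split is binary: reports where one
target drug is suspect and the other concomitant are background. Published
absolute results for a given drug pair depend on the full database
background (the b, c, d cells), so they cannot be reproduced from the
exposed cohort alone; the validation here is instead exact-arithmetic,
oracle-based and simulation-based.
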