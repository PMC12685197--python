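# Methods

## Study design being emulated

The pipeline reproduces a retrospective, cross-sectional analysis of
antihypertensive dosing in preterm neonates from an inpatient EMR
extract: three flat tables (visits, medication administrations at
minute resolution, weight measurements) are reduced to per-course dose
trajectories, which are clustered and characterized. Analysis units are
**treatment courses** — one drug's administrations within one visit.

## Cohort selection

A visit is included iff gestational age at birth < 37 weeks,
postmenstrual age at discharge < 44 weeks (strict inequalities on
decimal weeks), and at least one administration of one of 14 study
antihypertensives (hydralazine, nitroprusside, clonidine, enalapril,
captopril, propranolol, labetalol, esmolol, atenolol, metoprolol,
amlodipine, isradipine, nifedipine, nicardipine). Included visits are
then excluded for any IV propranolol administration (oral
bioavailability ≈ 25 % makes oral and IV trajectories incomparable) and
for a hemangioma discharge diagnosis in any position (an alternative
propranolol indication). Rules run in that order with first-failure
attribution; the exclusion ledger records every excluded visit and
reconciles exactly with the included/excluded partition. Diuretics are
deliberately not on the drug list (they would capture bronchopulmonary
dysplasia treatment rather than hypertension).

Comorbidity flags are exact matches of normalized ICD-9/10 codes
(upper-cased, trailing zeros after the decimal stripped) against
configurable lists; the hemangioma exclusion alone uses prefix
semantics (D18.0\*, 228.0\*) so that D18.1 (lymphangioma) never
matches. The patent-ductus-arteriosus list (747.0 / Q25.0) is a package
default, configurable like the rest. Unknown codes are ignored; when a
visit's diagnosis availability is flagged absent, all six flags are
missing rather than false.

## Trajectory construction

Weight assignment takes the measurement minimizing |t_weight −
t_admin|, averaging exact minute-level ties. Standardization is mg/kg
per administration (oral) and mg/kg/min (IV). The trajectory is a step
function on a left-closed hour grid anchored at the first
administration: hour *h* carries the standardized dose of the latest
administration before the end of hour *h*. Oral courses keep the last
dose for six hours after the final administration, then drop to 0
mg/kg; six hours is the modal dosing interval in this population. IV
courses have no six-hour tail: they end at an explicit rate-0 event,
or one hour (configurable) after the last rate event when no stop was
recorded — the rate-event representation of IV titration is an
assumption about how infusions appear in the administration record.

Regimen descriptors: min/max of per-administration standardized doses,
converted for oral drugs to mg/kg/day by 24 / (modal inter-dose
interval in hours), ties resolved to the smaller interval and a 6 h
interval assumed for single-dose courses; duration is last minus first
administration (the six-hour tail is excluded — a deliberate choice,
since the tail is a plotting convention, not treatment). A "dose
increase" is a strict increase in administered mass load (mg, or mg/min
for IV) versus the immediately preceding administration; the mean time
to increase averages gaps between consecutive increases with the first
gap measured from the first administration. Both descriptors are absent
when the mass load never increased.

## Window selection

Candidate windows default to every integer hour up to the longest
course (`observed_durations` uses the sorted distinct course lengths
instead). Each window w is scored by the sample SD (n−1 denominator)
of all C(n,2) pairwise Euclidean distances between curves sampled at
hours 0..w−1, zero past each course's end; at least 3 curves are
required. The chosen window is the profile argmax, ties to the smallest
window. A per-drug override returns the override while the full profile
and the unconstrained argmax are always reported — mirroring the
analyst decision needed when the global maximum sits at a degenerate
1-hour window. The n−1 SD cannot change the argmax relative to the
population SD (a constant factor); it is fixed for reproducibility.
Curves are not length-normalized before distance computation.

## Functional K-means

Curves are clustered as raw vectors on the common hourly grid — no
smoothing or basis expansion, consistent with the step construction.
Everything is deterministic:

* **max-dist seeding**: the first two seeds are the pair at maximum
  Euclidean distance; each further seed maximizes the minimum distance
  to the seeds chosen so far; all ties break to the smallest row index.
* **Lloyd iterations**: nearest-centroid assignment (ties to the lower
  label), centroid-as-mean update, at most 100 iterations; an empty
  cluster is repaired by moving in the point farthest from its current
  centroid (from a cluster with at least two members).
* **single-move polish**: after Lloyd converges, single reassignments
  are applied while any strictly lowers the partition objective
  (best improvement, ties to the smallest point index; moves that would
  empty a cluster are disallowed), re-entering Lloyd after each move.
  This step exists because a Lloyd fixed point need not be optimal
  under single reassignments — a point can profitably move from a large
  cluster to a small one even when it already sits nearest its own
  centroid (the size factors n/(n−1) and m/(m+1) shift the break-even
  point). The polish makes the returned partition 1-swap optimal while
  keeping the objective monotone; termination is guaranteed because
  each move strictly decreases the objective over a finite partition
  set.

Labels are re-lettered A, B, C, … by descending cluster size (ties to
the smallest member index) so "A" is always the largest cluster. Fits
are run at k = 2, 3, 4; no model-selection statistic is computed — all
three solutions are reported and the characterization tables default to
k = 3.

## Cluster characterization

Continuous variables: Kruskal–Wallis rank-sum test (tie-corrected, via
scipy), summarized as median (Q1, Q3) with linear interpolation between
order statistics. Categorical variables: Pearson chi-square without
continuity correction unless any expected count is below 5, then
Fisher's exact test; rows or columns that are entirely zero are dropped
before the rule is applied, and a table left with fewer than two rows
or columns gets no test (rendered N/A). Missingness is handled
per-variable (complete cases within a row) with missing counts
displayed; categorical percentages use non-missing denominators.

Fisher's test is two-sided by the minimum-likelihood criterion: the sum
of probabilities of all fixed-margin tables whose hypergeometric
probability is at most the observed table's (within 1e-7 relative
tolerance). 2×2 tables go through scipy; r×c tables are enumerated
exhaustively up to a configurable table-count cap (default 200,000),
beyond which a seeded Monte Carlo estimate using scipy's fixed-margin
table sampler is returned and flagged as simulated.

p-values are rendered compactly (">0.9" cap, "<0.001" floor, one
decimal when p rounds to ≥ 0.2, otherwise two significant figures with
trailing zeros kept) with full precision emitted alongside. No
multiple-testing correction is applied.

## Synthetic cohort generator

The generator emulates the study conditions: three agents (oral
propranolol ≈ 74 % of courses, oral captopril ≈ 11 %, IV esmolol
≈ 15 %), each with three planted archetypes whose shapes mirror the
clinically observed cluster morphologies —

| drug | archetype | pattern |
|---|---|---|
| propranolol | maintain (51 %) | hold 0.75 mg/kg q6h, 150–280 h |
| propranolol | low-titrate (30 %) | 0.4 mg/kg + 0.15 per 48 h to 1.0, 300–450 h |
| propranolol | high-start (19 %) | hold 1.25 mg/kg, 480–700 h |
| captopril | low-brief (50 %) | 0.15 mg/kg, 24–72 h |
| captopril | stepwise-up (30 %) | 0.15 + 0.10 per 72 h to 0.5, 250–400 h |
| captopril | fast-up (20 %) | 0.30 + 0.15 per 24 h to 0.9, 120–250 h |
| esmolol | short-low (64 %) | 0.05 mg/kg/min, 12–36 h |
| esmolol | long-moderate (22 %) | 0.10 + 0.02 per 12 h to 0.2, 80–140 h |
| esmolol | high-rapid (14 %) | 0.35 + 0.05 per 6 h to 0.5, 30–60 h |

Dose levels, titration steps, durations and postnatal start ages are
package defaults chosen once to bracket the reported medians and
interquartile ranges of this population (e.g. propranolol durations
spanning roughly 90–800 h around a ~300 h median); no per-archetype
distributions are published, so these are design choices, not fitted
values. The propranolol archetypes carry gestational-age ranges
(high-start: 26–31 weeks; others ≈ 29–36.5) to plant the clinically
observed covariate shift — infants needing high doses longer are born
more preterm and discharged older.

Mechanisms deliberately modeled:

* **mg/kg drift**: oral masses are recomputed from the intended mg/kg
  level only when the level changes and otherwise held fixed in mg, so
  standardized doses drift downward as the infant gains weight (default
  20 g/day on a GA-dependent birthweight); daily weight measurements.
* **noise**: each administration's standardized dose is perturbed by
  N(0, noise_sd) (default 0.05, in mg/kg or mg/kg/min), applied on top
  of the drifting mass level.
* **missingness**: birthweight missing in the visits table with
  probability 0.55, diagnosis availability absent with probability
  0.05, plus small missingness in sex/race/ethnicity — matching the
  heavy birthweight missingness typical of clinical data warehouses.
* **comorbidities**: independent Bernoulli flags at the population
  prevalences (BPD 0.32, PDA 0.35, CHD 0.54, pulmonary hypertension
  0.098, AKI 0.037, diagnosed hypertension 0.11), emitted as a random
  ICD-9 or ICD-10 representative code to exercise normalization.
* **exclusion spikes**: with small probabilities a patient is emitted
  term (GA 37.5–41), given a stray IV propranolol administration, or a
  hemangioma code — records the selection stage must remove.

Determinism: one root seed; patient *i* draws from the substream
`SeedSequence([seed, i])`, so row order never affects draws and a fixed
seed yields byte-identical CSVs.

What the generator does **not** emulate: correlated comorbidity
structure (flags are independent), blood-pressure response or any
outcome process, irregular dosing schedules (oral courses are strictly
q6h), transcription errors, or multi-visit patients (one visit per
patient; an optional co-therapy flag can emit esmolol-then-propranolol
sequences within a visit, off by default). Passing recovery tests
therefore show the pipeline recovers planted structure under realistic
noise, drift and missingness — not that real cohorts contain three
clean archetypes per drug.

## Numerical choices

* Quantiles: linear interpolation between order statistics (numpy
  default) throughout.
* The noise-free, constant-weight round trip (generator → trajectory)
  is checked at 1e-12 absolute tolerance: reconstruction divides the
  emitted mass by the same weight it was multiplied by, which is exact
  up to one floating-point ulp per administration.
* WCSS monotonicity is asserted at 1e-9 relative tolerance to absorb
  accumulation error in the objective.
* K-means assignment ties go to the lower cluster label; maximin and
  relabeling ties to the smallest row index; window-score ties to the
  smallest window — every tie rule is fixed so identical inputs give
  identical outputs.
* Degenerate inputs: fewer than 3 curves cannot be window-scored; a
  course mixing oral and IV rows raises a course-splitting error (the
  study object then splits it per route); all-identical K-means inputs
  exercise the empty-cluster repair and return a zero-WCSS solution.

## Problem sizes

Default runs use 100 synthetic patients (≈ 90 included visits, ≈ 70
propranolol courses — the scale of a large single-center neonatal
cohort); recovery checks use 70 single-drug courses over 20 seeds; the
test-statistic oracles sweep all 2×2 tables with margins ≤ 12 and 100
random small samples. These sizes were chosen as the smallest that
exercise every code path at the cohort scale the method targets.

## Known limitations

* The window-selection override is an analyst decision; the package
  only reports the profile and both windows, it does not detect local
  maxima automatically.
* Fisher's exact test beyond enumeration range is Monte Carlo with a
  fixed seed (flagged in the result), not a network-algorithm exact
  computation.
* IV regimen "mean dose increase" is in mg/min (rate deltas), not mg —
  the administered-quantity column is route-dependent.
* No pharmacokinetic modeling: trajectories describe administered
  weight-based dose, not exposure.
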