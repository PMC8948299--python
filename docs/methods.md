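# Methods

This note records the scientific model behind `mmclust`, the defaults and
why they were chosen, and the places where a design was genuinely open.

## Cohort model

The input is an episode table: one row per inpatient admission with a
patient identifier, record type (general/acute or psychiatric), admission
and discharge dates, admission type (routine, emergency, day case,
obstetric), one main plus up to five other ICD-10 diagnoses, sex, birth
date, deprivation quintile (1 = most deprived) and sixfold urban–rural
class.

**Index admission.** A patient's index admission is their earliest
general/acute admission of type routine or emergency in the study year
(default 2014). Day-case, obstetric and psychiatric admissions never start
a cohort membership; episodes with a blank identifier are unlinkable and
dropped first; patients under 18 completed years at the index date are
excluded. Equal index dates resolve by file order — administrative extracts
are episode-ordered, and a deterministic rule is required for testing. All
drops are counted, and the counts must conserve (input = retained + dropped
at every filter); this is asserted at run time and recorded in the run
manifest.

**Condition ascertainment.** The 30 chronic conditions of a Tonelli-style
administrative coding scheme are flagged by leading-prefix match of
normalised (uppercase, dot-free) ICD-10 codes, with main and other
diagnosis positions weighted equally. The packaged catalog is an
implementer-curated approximation spanning all 30 conditions (its version
string says so); any two-column `condition,icd10_prefix` CSV can replace
it. Cross-condition prefix nesting is rejected at load so mapping needs no
longest-match rule; the metastatic/non-metastatic cancer split relies on
the disjoint ICD-10 ranges C77–C80 vs named-site codes. Prefix granularity
cannot express "peptic ulcer excluding bleeding" exactly; the catalog keeps
K25–K28 whole.

Conditions are collected from **all** record and admission types — the
psychiatric stream is excluded from index identification yet contributes
diagnoses — over the half-open window `[index − 5 years, index)`. "Five
years before" means the same month/day five years earlier (Feb 29 anchors
to Feb 28). The index admission's own diagnoses are excluded by default:
with a strictly-prior ascertainment convention a condition first coded on
the index date is unobservable, and making the convention explicit makes it
testable. `include_index_admission=True` selects the alternative reading
(window closes at the end of the index day). Same-day pre-index episodes
fall outside the default window for the same reason.

Multimorbidity is ≥ 2 flagged conditions (configurable).

## Dissimilarity

Condition vectors are binary, so the Gower dissimilarity with asymmetric
binary treatment reduces to the Jaccard distance
`d(x, y) = 1 − |x ∧ y| / |x ∨ y|`: two patients are not similar merely for
both lacking a rare condition. Jaccard is undefined for an all-zero vector;
the multimorbid cohort guarantees ≥ 2 positives per row, and the
implementation rejects zero rows by name. The Hamming distance
(mismatch fraction; equal to the symmetric all-weights-one Gower
coefficient) is the sensitivity alternative — it counts joint absences as
agreement, which inflates similarity between patients with few conditions.
Pairwise computation is delegated to `scipy.spatial.distance`.

**Hopkins statistic.** Per repetition, `m = max(10, round(0.1 n))` probes
(capped at 100) are drawn from the cohort; `w_i` is each probe's distance
to its nearest other real row, `u_i` each reference row's distance to its
nearest real row, and `H_rep = Σw / (Σu + Σw)`; the statistic averages 25
repetitions. Orientation: ≈ 0.5 structureless, → 0 clustered (the
complement is exposed for users of the opposite convention). Two reference
schemes exist because binary space has no canonical "uniform" null:
`marginal` (default) draws each condition Bernoulli at its observed
prevalence — the no-association null with realistic marginals — while
`uniform` uses Bernoulli(0.5), which is wildly unrepresentative when
prevalences run 1–56 %. The degenerate all-duplicates limit (every w = 0)
is defined as H = 0 even when degenerate marginals make the reference
coincide with the data. Hopkins uses the same metric as the downstream
clustering run for internal consistency. Calibration (tested): Bernoulli
(0.5) noise at n = 500 gives H ≈ 0.50; ten planted well-separated groups at
n = 1000 give H ≈ 0.26.

## Clustering

**PAM.** Classic Kaufman–Rousseeuw BUILD + SWAP. BUILD: the first medoid
minimises total distance to all points; each later medoid maximises the
additional cost reduction. SWAP: repeatedly apply the single
(medoid, non-medoid) exchange with the largest strict cost decrease
(tolerance 1e-12) until none exists. Every tie — BUILD candidate, SWAP
pair, nearest-medoid assignment, best k — breaks to the lowest row index /
smallest k, making results reproducible bit-for-bit. Each medoid leads its
own cluster even under all-zero distances. The swap search is vectorised
(O(n²) per iteration via cached nearest/second-nearest distances and
per-cluster group sums); the per-step cost is O(k (n − k)²), which targets
desk-scale n in the thousands rather than full-population extracts.
Accelerated variants (FastPAM-style) and sampling (CLARA) were deliberately
not used: determinism and auditability beat speed at this scale.

A caveat verified during development: best-improvement single-swap PAM is a
*local* search. On roughly 10 % of small random dissimilarity matrices its
certified local optimum (no single exchange improves — asserted by a
brute-force certificate in the tests) is not the global optimum over all
medoid subsets. R's reference `cluster::pam` returns identical costs on the
same instances, including the non-global ones; the test suite pins our
implementation to both oracles (exhaustive minimum where attained, R
agreement always, local-optimum certificate always).

**Silhouette.** `s(i) = (b − a) / max(a, b)` with a = mean within-cluster
distance (excluding self) and b = the smallest mean distance to another
cluster; singletons and the degenerate a = b = 0 case score 0 (Rousseeuw's
convention, kept for continuity). The average is unweighted. k is chosen to
maximise the average over the grid 2–15 by default — wide enough to bracket
the ten groups of the reference cohort without assuming them.

**Adjusted Rand index.** Standard permutation-model chance correction from
the contingency table; two structurally trivial identical partitions define
ARI = 1. Used for sensitivity comparisons and generator-truth recovery.

**Sensitivity variants.** (1) Hamming distance; (2) drop the single most
prevalent condition; (3) drop conditions below 5 % prevalence. Patients are
retained even if column removal leaves them below two conditions — the
variants redefine the clustering feature space, not the cohort — but rows
left all-zero must be excluded from Jaccard variants and are counted in the
report. Each variant reports its chosen k, ARI against the baseline
partition on the shared rows, and a cross-tabulation.

## Synthetic data generator

The generator emulates a linked hospital-episode extract: a 2014 index
cohort with five years of history, 30 chronic conditions, demographic
structure and small missingness rates.

* **Mixture.** Each patient is multimorbid with probability 0.274 (the
  reference cohort's rate). Multimorbid patients draw a group from K
  weights, then a condition vector from the group's Bernoulli profile,
  rejection-sampled until ≥ 2 conditions (budget 1000 draws; a profile too
  sparse to reach 2 raises an error). Rejection rather than renormalisation
  keeps the per-condition profile interpretation, at the cost of slightly
  inflated marginals. Background patients carry one condition with
  probability 0.241 (sampled from the mixture-average prevalence) or none,
  so the multimorbidity filter has realistic work to do.
* **Defaults are the reference cohort.** `default_profiles()` returns ten
  group weights proportional to the published group sizes (2590 … 508 of
  11,389), the 10 × 30 profile matrix equal to the published per-group
  prevalences / 100, and per-group demographics (median/IQR age, sex,
  deprivation, urban–rural, emergency proportion) plus a background stratum.
  `well_separated_profiles()` builds the idealised recovery benchmark:
  equal weights, each group owning 3 of 30 conditions at probability 0.9,
  all others 0.05.
* **Episode placement.** Each patient gets one index admission in the study
  year carrying a neutral acute code that maps to no catalog condition —
  planted conditions must never be visible on the index date, which makes
  the lookback convention testable. Each present condition generates
  `1 + Poisson(mean − 1)` prior admissions (default mean 1.5), uniformly
  dated in the lookback window, carrying a code drawn from the condition's
  prefixes; ~30 % of prior admissions co-code other present conditions in
  the spare diagnosis slots. Prior admissions with F-chapter main codes are
  psychiatric records half the time (exercising the SMR04-style inclusion
  rule); prior admissions that land inside the study year are emitted as
  day cases so they cannot displace the planted index admission.
* **Demographics.** Ages are truncated-normal per group (location = median,
  scale = IQR/1.349, truncated to [18, 105]); exact quantile matching is
  not attempted. Birth dates are back-dated so completed years at index
  equal the drawn age. Deprivation and urban–rural classes are categorical
  draws from the group weights.
* **Missingness.** Per episode, the identifier is blanked with probability
  0.01; per patient, deprivation and urban–rural are blanked with
  probability 0.01 — the same order of magnitude as the linkage losses of
  the reference extract.
* **Not modelled.** Within-group residual dependence between conditions
  beyond mixture membership; realistic code-frequency distributions within
  a condition; seasonality; mortality. Passing recovery tests therefore
  shows the pipeline recovers *mixture-style* structure, not that real
  hospital data has such structure.

With missingness off, the generator→cohort round trip is exact: the
ascertained binary matrix equals the planted truth row-for-row (tested at
n = 2000).

## Labelling rule

Published prevalence tables of this kind annotate, per patient group, the
dominant conditions (bold) and over-represented minor conditions (italic).
The deterministic reconstruction used here:

* **Cluster conditions**: prevalence ≥ 50 % within the group (threshold
  configurable). Against the packaged reference table this reproduces every
  annotated dominant cell exactly (every bold value is ≥ 53.2, every other
  < 50). If no condition reaches the threshold the single most prevalent
  condition stands in, so a label always exists.
* **Label**: base name of the most prevalent condition, with comma
  qualifiers and parentheticals stripped ("Cancer, non-metastatic (…)" →
  "Cancer"); conditions tied at the group maximum are joined with "/",
  which yields "Chronic kidney disease/diabetes" (both 100 %) next to a
  plain "Chronic kidney disease" group. If two groups still share a label,
  each appends its next-highest cluster condition.
* **Feature conditions** (explicitly an approximation — the original
  annotations came from clinical review): a non-cluster condition features
  in the group where it attains its maximum prevalence among groups where
  it is not a cluster condition, provided that prevalence is ≥ 1.25× its
  overall prevalence. This reproduces most but not all reference italics
  (e.g. it also flags stroke in the hypertension-led group); both knobs are
  configurable.

Group characteristics use median/quartiles by linear interpolation
(numpy's default, R type 7), condition-count bands {2, 3, 4, 5+}, and
percentages over non-missing values for deprivation and urban–rural with
missing counts reported separately.

## Pipeline and reproducibility

One top-level seed feeds a numpy `SeedSequence`; the simulation and Hopkins
stages get spawned substreams, so any stage can be re-run in isolation with
identical output, and re-running a config reproduces numeric artefacts
byte-for-byte. The manifest records the config snapshot, seeds, stage
timings, per-stage row counts (with conservation), the Hopkins result,
chosen k and group labels. Stage failures raise an error naming the stage
and leave a `FAILED` marker beside any partial artefacts. The t-SNE `embed`
subcommand is a presentation-only hook delegating to scikit-learn when
available.

**Problem sizes.** Tests and the acceptance script run the generator at
n = 300–4000 patients and the clustering at up to n = 2000 multimorbid
rows with the default k grid — sizes chosen so the full suite completes in
a few minutes on one core while keeping Monte-Carlo checks (multimorbid
fraction ± 0.03, per-group prevalence deviation ≤ 0.05, Hopkins bands)
well-powered.

## Known limitations

* The packaged catalog approximates the validated coding scheme; users with
  the exact list should supply it as a file.
* PAM local optima (above); an optional restart mode is not provided in the
  deterministic pipeline.
* The feature-condition (italic) rule cannot recover clinical-review
  judgement exactly.
* Synthetic demographics are independent of the condition vector given the
  group, which real data violates (e.g. age–condition correlation within a
  group).
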