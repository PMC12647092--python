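# Methods

This note records the statistical and computational choices behind
`faersig`: the models, the defaults and why, what the synthetic generator
does and does not emulate, and the numerical conventions.

## Counting model

All disproportionality statistics are computed over **(report, distinct
PT)** pairs derived from the reaction table of the deduplicated dataset.  A
report listing k distinct preferred terms contributes k pairs; a PT
repeated within one report counts once.  For a drug–PT pair, `a` is the
number of pairs from the drug's cohort carrying that PT, `a+b` the cohort's
total pairs, `a+c` the PT's total pairs over the whole background, and `N`
the grand total.  The background is always the full dataset, a superset of
every cohort.  Reports without reactions contribute no pairs but remain in
the dataset for the descriptive layer.

## Deduplication

Spontaneous-report databases carry multiple versions of a case.  The rule
used is the community-standard one: group DEMO rows by case id, keep the
row with the latest FDA receipt date, and break ties by the numerically
largest primary id.  Rows without a case id cannot be grouped and are kept
as singletons (counted separately).  The operation is idempotent, and the
retained set is independent of input row order.

## The four algorithms

* **ROR** ad/bc with a Wald interval on the log scale.  Positive:
  95% CI lower bound > 1 and a > 3.
* **PRR** [a/(a+b)]/[c/(c+d)] and the uncorrected Pearson chi-square
  (no continuity correction; the statistic equals Σ(O−E)²/E over the four
  cells, asserted in tests against an independent oracle).  Positive:
  PRR > 2, χ² > 4, a > 3.
* **BCPNN**.  Point estimate IC = log₂(a·N/((a+b)(a+c))).  The credibility
  bound uses the closed-form Dirichlet scheme with hyperparameters
  (α₁, β₁, α, β, γ₁₁) = (1, 1, 2, 2, 1):

      γ     = γ₁₁ (N+α)(N+β) / ((a+b+α₁)(a+c+β₁))
      E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
      V(IC) = (1/ln 2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                        + (N−a−b+α−α₁)/((a+b+α₁)(1+N+α))
                        + (N−a−c+β−β₁)/((a+c+β₁)(1+N+β)) ]
      IC025 = E(IC) − 2·√V(IC)

  Shrinkage pulls sparse cells toward independence and vanishes as counts
  grow (IC025 → IC; the credibility gap decays roughly like 1/√a, checked
  numerically).  Positive: IC025 > 0.
* **EBGM** is implemented in its simplified relative-reporting-ratio form
  a·N/((a+b)(a+c)) with a log-normal 95% interval
  exp(ln EBGM ± 1.96·√(1/a+1/b+1/c+1/d)).  This is deliberately *not* the
  full DuMouchel gamma–Poisson mixture: no shrinkage is estimated, and the
  point estimate is identically 2^IC of the same table (asserted in tests).
  Positive: EBGM05 > 2.

The "N > 3" report-count criterion is read as a > 3 — the case count of the
target pair — the conventional reading in this literature; the threshold is
configurable.

**Zero cells.**  Default policy is `strict`: when a zero cell makes a
standard error incomputable the statistic is reported as NaN and can never
be positive.  (The a > 3 criterion already excludes the affected pairs from
positivity.)  The Haldane–Anscombe +0.5 correction is available as
`zero_cell_policy="haldane"`, off by default.

**Classification.**  `any_positive` = at least one algorithm fires;
`strong` = all four.  No multiple-testing correction is applied — the
four-way consensus rule is the false-positive guard, and the null
calibration below quantifies it.  Ranked listings order by descending a,
then descending ROR, then PT lexicographically.

A note on monotonicity: ROR and PRR are strictly increasing in a with
b, c, d fixed.  The observed-to-expected ratio behind IC and EBGM is not —
it tends to 1 as a dominates its margins — so only the direction-agreement
property (sign of ln ROR, ln PRR, IC all follow sign(ad − bc)) holds for
all four.

## Descriptive layer

Percentages are count/denominator rounded **half-up to two decimals**.
Sex, age, reporter and country blocks use the cohort report count as
denominator.  The outcome block uses the number of outcome *entries* — one
per (report, outcome code) — because one report can carry several outcome
codes; this is also how published characteristics tables in this area sum.
Both the full seven-code outcome view and the severe subset
{death, life-threatening, hospitalization, disability} are emitted.

Age bins are half-open: [0,18), [18,65), [65,∞) — printed "18–65 / ≥65"
ranges double-book the boundary, so 65.0 falls in the upper bin.  Age unit
codes convert as YR×1, DEC×10, MON×1/12, WK×1/52, DY×1/365, HR×1/8760;
negative or unparseable ages become unknown.

Time-to-onset is event date minus the earliest therapy start of a target
drug, in whole days, binned [0,7], (7,28], (28,60], (60,∞).  Only complete
8-digit dates enter the arithmetic; partial (YYYYMM/YYYY) or missing dates
and negative onsets are excluded and counted.  Six- and four-digit dates
still contribute their year to annual trends.

Reporter categories are carried verbatim and never merged, so a source
table that lists the same label twice (as published characteristics tables
sometimes do) keeps two rows; the marginal-count replay constructor
(`profile_from_counts`) takes ordered (label, count) sequences for exactly
this reason.

## Drug matching and cohort membership

Matching normalizes case, punctuation and whitespace and compares the whole
normalized drug-name and active-ingredient fields against the targets;
substring matching is available but off by default, since keyword searching
of verbatim drug names is ambiguous.  Primary- and secondary-suspect roles
count by default; concomitant drugs do not (configurable).  An optional
indication-based PT exclusion filter exists but defaults off: published
analyses in this area generally do not remove PTs equal to the treated
indication, which is why the indication itself can surface as a top signal.

## Network stage

Edge lists are (node, node, combined score); scores above 1 are assumed
STRING-style 0–1000 and rescaled (logged).  Filtering drops edges below the
threshold (default 0.700) and then isolated nodes.  MCC uses exact maximal
clique enumeration (Bron–Kerbosch with pivoting via networkx); exponential
worst case, guarded by a 2,000-node cap.  The RWR iterates
p ← (1−r)·W·p + r·p₀ with W the column-normalized adjacency of the
*binary* thresholded graph (a score-weighted walk is available), p₀ uniform
over seeds, L1 tolerance 1e−10, max 10,000 iterations; non-convergence
raises with the last residual.  r defaults to 0.75, the default of the R
`dnet` implementation commonly used for this analysis.  Affinity ranking
excludes seeds by default (flag to include).  A converged vector is checked
against the direct solve of (I − (1−r)W)p = r·p₀ in tests.

## Synthetic generator

The generator emulates the *structure* of quarterly spontaneous-report
extracts, not their content: seven tables per quarter in the same dialect,
drugs drawn independently per report by marginal use probability, PTs drawn
independently at background × RR rates (RR > 1 only for planted drug–PT
signals), categorical demographics, Bernoulli outcome codes, uniform
receipt/start dates within the quarter, Weibull onset days, planted
same-case duplicates with earlier receipt dates, and partial event dates.
Reports whose drug draws all come up empty receive a catch-all filler drug
rather than being resampled, which keeps every catalog drug's marginal
probability exact and makes the closed-form contingency expectations
(exact enumeration over drug subsets) an analytic oracle.

Defaults were chosen once as plausible study conditions for a mid-sized
neurology cohort: target-drug use probabilities 0.10/0.12/0.04 plus common
co-medication (0.20–0.30), ~30 PTs with background rates 0.002–0.05
(grand background pair rate ≈ 0.47 per report), sex M/F/unknown =
0.45/0.35/0.20, 65% known ages ~ N(58, 14²), a US-dominated country mix,
consumer-led reporter occupations, outcome-code rates led by
hospitalization (0.30) and death (0.28), 5% duplicates, 10% partial event
dates, and Weibull(shape 1.2, scale 45 days) onsets.  Infeasible configs
(background × RR > 1) fail loudly, naming the pair.  Identical config and
seed produce byte-identical files.

What the generator does **not** emulate: real reporting heterogeneity
(correlated drug–PT structure, secular trends, country-specific coding),
MedDRA versioning, narrative fields, or the legacy pre-2012 schema.
Passing recovery tests therefore demonstrates correctness of the pipeline's
arithmetic and bookkeeping under a known model — not robustness to the
biases of real spontaneous data (under-reporting, duplicates that differ in
content, channeling).

The experiment sizes used by the test suite and the reproduction script —
50,000 reports for recovering planted RR ∈ {2, 5, 10} within ±3 SE of
ln RR, and 10,000 reports × 50 PTs for the ≤1% null strong-signal rate —
were chosen so that planted effects are estimable with comfortable margins
while a full run stays in the tens of seconds.  At these settings an RR=2
signal is typically *positive* but not *strong* (EBGM05 rarely clears 2 at
a true ratio of 2), which reflects the thresholds, not an implementation
limit.

The deterministic marginal-replay constructor (`cohort_from_marginals`)
builds a cohort with exactly specified block counts, assigning each
categorical block independently and laying outcome codes out cyclically so
no report repeats a code.  It exists because sampled cohorts match marginal
percentages only in expectation, while the descriptive layer's arithmetic
can be checked exactly against published tables.

## Known limitations

* EBGM is the printed simplified form, not gamma–Poisson shrinkage; no
  empirical-Bayes FDR, no stratified (age/sex) analyses.
* Deleted-case lists and the legacy pre-2012 schema are not handled.
* MCC is exact and therefore capped; very large PPI networks need
  pre-filtering.
* The cross-drug death-share arithmetic reproduces whatever the input
  marginal counts imply; published prose occasionally disagrees with its
  own table sums (e.g. an overall death share printed as 40.02% where the
  table's sums give 1318/3279 = 40.20%), and this package reproduces the
  sums.
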