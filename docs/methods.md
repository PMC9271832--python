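# Methods

## Data model

The canonical exchange format is a tidy long table: one row per
participant × visit × story (A/B) × item (1–25) × recall condition
(immediate/delayed) with a binary `correct` score. Dates are accepted
as ISO-8601 or decimal years and carried as decimal years, since
visit-to-scan gaps are naturally reported in years. Rows with a missing
`correct` are dropped with a logged count; an item's indices at a visit
are computed over the participants with a non-missing response to that
item, and discrimination over the complete cases within its rest-score
scope. Validation is report-only: incomplete item sets, orphan
participant ids and taxonomy gaps are flagged, never silently repaired.

Amyloid status is a strict dichotomization of the global PiB DVR:
positive iff DVR > 1.19, so a value exactly at the threshold is
negative. For the PET-matched analyses each participant contributes the
recall assessment closest in time to the PET scan; equidistant ties go
to the earlier visit by default (configurable), a choice the source
design leaves open.

## Item taxonomy

Serial position is a pure function of the item index: items 1–8
"primacy", 9–17 "middle", 18–25 "recency" (8/9/8 per story). Lexical
categories partition the 50 idea units into 9 proper names, 14 verbs,
4 numerical expressions and 23 "other"; these aggregate counts are
validated on load. The *per-item* assignments bundled with the package
are illustrative: they satisfy the counts and spread plausibly over
stories and positions, but published scoring templates do not print the
item-by-item mapping, so users replicating a specific instrument should
supply their own taxonomy file (CSV/TSV/YAML/JSON with story, item,
category).

## Indices

Difficulty is the proportion correct. Discrimination is the corrected
item-total correlation: Pearson correlation (point-biserial in form)
between the binary item and the rest-score. The rest-score spans all 50
items of the same condition and visit by default — matching the
50-item total-score framing — with a per-story option
(`rest_score_scope="per_story"`). Zero-variance items propagate as
missing (flagged), never as 0, and are excluded from aggregates with
logged counts; computing discrimination requires at least 3 complete
cases.

Aggregation treats the *item* as the unit of analysis: per stratum
(story, lexical category, or serial position) the unweighted mean and
sample SD (ddof = 1; 0 for a singleton stratum) over member items'
indices. Cross-visit summaries are unweighted means of per-visit
indices, so visits with fewer participants are not down-weighted; both
choices mirror how item-level tables pair and average items rather than
responses. Condition differences are stored as immediate − delayed for
difficulty (positive = harder at delay) and delayed − immediate for
discrimination (positive = more discriminating at delay); an additional
`plot_difficulty_change` column carries the plotted convention
(delayed − immediate).

## Group contrasts

Cliff's delta is computed by exact sign enumeration over all cross-group
pairs; ties contribute zero. Magnitude bands are half-open:
[0, 0.147) negligible, [0.147, 0.33) small, [0.33, 0.474) medium,
[0.474, 1] large.

Test selection: for unpaired contrasts the parametric branch
(independent t) requires both samples to pass Shapiro–Wilk normality
and the pair to pass Brown–Forsythe (median-centered Levene)
homogeneity, each at `assumption_alpha` (default 0.05); otherwise
Mann–Whitney U. For paired contrasts the gate is Shapiro–Wilk on the
pairwise differences; otherwise Wilcoxon signed-rank. The exact
rank-test null distribution is used when min(n) ≤ 25 with no ties, else
the continuity-corrected normal approximation. All tests are two-sided;
no multiplicity adjustment gates the primary flags (a Holm-adjusted
column is emitted alongside). Degenerate inputs (both samples constant,
or all paired differences zero) raise rather than fabricate a p-value.

The amyloid contrast suite computes, per recall condition and index
type, contrasts for the overall item set, each story, each lexical
category and each serial position (2 × 10 = 20 per index type). Items
are the pairing unit: the subset's per-item indices in the
amyloid-positive group are paired with the same items' indices in the
negative group, positive group first, so "harder for amyloid-positive"
appears as negative delta. An unpaired variant of every contrast is
emitted as a secondary analysis (`variant` column) because captions of
the figure-level overall comparisons are ambiguous about pairing;
the paired rows are primary. Subsets with fewer than 3 defined pairs
are reported descriptively without a test.

## Repeated-measures models

Index models: `index ~ story + lexical_category + serial_position`
with a random intercept per item across visits, reference levels story
A / proper name / primacy. The default family is a Gaussian likelihood
on the logit-transformed index, with indices clipped to
[0.005, 0.995] first; discrimination (range [−1, 1]) is mapped through
(r + 1)/2 before the transform. The logit-Gaussian default was chosen
because it is verifiable against closed-form least-squares oracles; a
beta-likelihood mixed model would be a plausible alternative for
sensitivity analysis but is not implemented here.

Omnibus factor tests are Wald F-tests from the REML fit with
between-within denominator degrees of freedom (number of items minus
fixed-effect rank). The factors vary *between* items, so the item count
— not the item × visit observation count — carries the information; an
ML likelihood-ratio chi-square here is measurably anticonservative
(per-factor type-I ≈ 0.07–0.08 at 50 items × 3 visits versus
0.043–0.057 for the between-within F at the same design). Post-hoc
pairwise contrasts are differences of level coefficients (equal to
marginal-mean differences in this additive treatment coding) with
unadjusted Wald p-values as primary and Tukey studentized-range
adjusted p-values as a secondary column, estimates on the model's
transformed scale.

With a single distinct visit there is no repetition to absorb and the
fit degrades to ordinary least squares with a logged note and
random-intercept variance 0; its coefficients equal the direct
least-squares solution to numerical precision.

The condition-change model fits the paired immediate-minus-delayed
differences on the natural index scale as intercept + story version
with a per-item random intercept: the intercept tests whether the mean
change differs from zero, the story coefficient whether the change
differs between versions. (Published coefficient tables for this
analysis show an apparent factor-of-ten scale inconsistency between the
reported mean change and the reported intercept; this package reports
everything on the natural index scale.)

## Synthetic cohort generator

Participant *p* recalls item *i* in condition *c* at visit *v* with
probability

    logistic( a_i (θ_p + ε_pv − b_i − δ·1[c = delayed] − γ_{cat(i),c}·1[p ∈ Aβ+]) )

with θ_p ~ N(0, σ_θ²) and ε_pv ~ N(0, σ_v²). Defaults: σ_θ = 1,
σ_v = 0.3 (visit effects are exchangeable perturbations — no practice
or learning drift), amyloid prevalence 0.23, PET scans for 338/1141 of
participants, biennial visits with each participant completing a
uniform 1..n_visits of them, and DVR drawn on the matching side of the
1.19 boundary with half-normal spread 0.15. Marginal ("expected")
difficulties integrate the logistic over the N(0, σ_θ² + σ_v²) ability
distribution by 201-node Gauss–Hermite quadrature, accurate beyond 6
significant digits, and serve as the oracle for calibration tests.

The item bank is deterministic (no sampling). Immediate-recall
difficulty targets per lexical category: proper names 0.43–0.92, verbs
0.40–0.90, numbers 0.50–0.74, "other" 0.22–0.88, evenly spaced within
category — means and spreads match the per-category descriptive
statistics reported for cohorts of this kind, and the even separation
ensures that item identity rather than sampling noise decides
cross-group rank comparisons even in the 4-item numbers subset. Slopes
rise with easiness for proper names (0.9–2.1) and numbers (0.8–2.0)
and cycle through fixed grids for verbs and "other". Item locations
b_i are solved from the targets by root-finding against the quadrature
oracle; the delay shift δ is solved so the mean expected difficulty
drop from immediate to delayed is 0.056; the single default amyloid
effect γ(proper_name, delayed) is solved so amyloid-positive
participants lose 0.103 expected proportion correct on delayed proper
names. Each participant consumes an independent substream
(`SeedSequence(seed, spawn_key=(index,))`), so enlarging a cohort never
reshuffles existing participants.

### What the generator does and does not emulate

It reproduces the first-moment structure the analyses consume: the
difficulty spectrum, the immediate-to-delayed shift, a
category-by-condition amyloid deficit, visit-level repetition, and a
prevalence-matched PET subsample. It does *not* model narrative
dependence between items (responses are conditionally independent
given ability), practice effects, demographic confounding, or
time-varying amyloid status. Two quantitative limits worth knowing:

- with a constant latent delay shift, the generator cannot produce a
  *wide* immediate proper-name spread and a *compressed* delayed spread
  simultaneously (the differential drops would have to exceed the mean
  drop), so delayed-recall contrast effect sizes sit nearer the medium
  boundary than the large values reported for real cohorts;
- within-category item *discriminations* cannot be separated much
  beyond their sampling noise at realistic slopes, so null Cliff's
  deltas for discrimination in small subsets are noisier than for
  difficulty.

Passing tests on this generator therefore demonstrate correctness and
calibration of the machinery, not that real recall data satisfy the
model's assumptions.

## Problem sizes and numerical choices

Calibration and operating-characteristic tests run at n = 1000–2000
participants with 100 replicates for suite-level checks, 500 replicates
for mixed-model null calibration, and ≥1000 simulations for the
test-selection branch; these sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping the default test run fast.
Quadrature uses 201 Gauss–Hermite nodes; location/shift calibrations
use Brent root-finding to 1e-8–1e-10; index clipping before the logit
uses ε = 0.005; mixed-model optimization falls back lbfgs → cg →
powell, and non-convergence is flagged in the result rather than
silently replaced. All output tables are written with a fixed float
format and sorted keys, making full pipeline runs byte-for-byte
reproducible for a given seed.
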