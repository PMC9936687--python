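# Methods

## The comparison

Every analysed dispatch carries two binary urgency labels. The dispatcher
side is the dichotomised dispatch priority: A/B (lights-and-siren) urgent,
C/D non-urgent. The EMS side is a rule-based reference standard applied to
what actually happened on scene. The analysis set is restricted to missions
completed with the patient confronted; cancelled, aborted,
patient-not-confronted, first-responder and invalid-data dispatches are
excluded but retained with a per-reason tally, so the exclusion count is
auditable. Unparseable CSV rows are likewise kept with status
`invalid_data` and a row/field/reason parse report rather than silently
dropped.

## Reference standard

Evaluation order (first satisfied rule wins, recorded in the
classification trace):

1. **Paramedic override.** A documented crew assessment *is* the label.
   Nothing else can change it; this primacy is property-tested.
2. **A/B dispatch:** urgent if transported with A/B priority, or deceased,
   or given significant treatment (regardless of transport); else
   non-urgent.
3. **C/D dispatch:** urgent if transported with A/B priority, or not
   transported but given significant treatment; else non-urgent — including
   routine C/D transport (even with treatment, since the treatment rule for
   this stratum literally requires non-conveyance) and death on scene.

*Significant treatment* is a disjunction of eight condition∧intervention
conjunctions: SpO₂ < 95 % ∧ bronchodilators; convulsion ∧ anticonvulsant;
allergic reaction ∧ epinephrine; airway management; CPR; glucose
< 4 mmol/L ∧ IV glucose; SpCO > 5 % ∧ oxygen; overdose/poisoning ∧
antidote. A missing vital never satisfies its criterion — "not measured" is
parsed as an explicit missing state, distinct from zero.

Two readings were genuinely open and are resolved as follows. An A/B
transport after a C/D dispatch is classified urgent (producing a false
negative for the dispatcher); the criteria table can also be read the other
way, so `cd_ab_transport_urgent=False` selects the alternative. Death after
a C/D dispatch is non-urgent, mirroring the paired urgent rule for A/B
dispatches. Correctness of the whole classifier is asserted against an
independent flat transcription of the criteria on an exhaustive grid of
field combinations, including the threshold-adjacent vitals 94.9/95.0,
3.99/4.0 and 5.0/5.01.

## Metrics

The dispatcher label is the test positive, the reference label the
condition positive — fixed and asserted in tests, since swapping them
swaps PPV with sensitivity. Over- and under-triage are implemented as
FP/(TP+FP) and FN/(TN+FN), so over + PPV = 100 and under + NPV = 100 hold
exactly before rounding. Intervals are Wald normal approximations with
z = 1.96 (via `statsmodels.proportion_confint`, clamped to [0, 100] in
percent); Wald was chosen because it reproduces every published interval
bit-for-bit at one-decimal rounding, and the Wilson score interval is a
configuration away for small or extreme proportions where Wald is poor.
A zero denominator makes a metric undefined; it is carried as `None` and
rendered `N.A.`. Internal values stay full precision; report rendering
rounds half-up to integer percent (CIs to one decimal), matching how such
tables are conventionally printed.

**Known discrepancy.** The source register's published overall specificity
(71 %, CI 69.3–71.1) does not follow from its own crosstab: TN/(TN+FP) =
3949/5602 = 70.5 %, Wald CI ≈ 69.3–71.7, and the printed upper bound even
lies below the point estimate. A typo is the likely explanation; the
package computes and reports the recomputed value and makes no attempt to
reproduce the printed one.

## Category statistics

Categories with strictly more than 50 dispatches enter the formal tests
(51 qualifies, 50 does not — the smallest real category has n = 51).
The χ² test is Pearson's without continuity correction on the 4×2
priority-by-label table, as the headline p-value attaches to that table;
the dichotomised 2×2 is available from the same report. The
Kruskal–Wallis H test runs on per-record confusion-cell codes (TP=1, FP=2,
TN=3, FN=4 in listing order — a convention, not a fact about the source
analysis, and an explicit parameter) grouped by category, with tie
correction; record-level scoring is the only reading under which
26 categories give df = 25. Dunn's rank-based z-test with Bonferroni
adjustment (`min(1, p·n_pairs)`) is the post hoc, the conventional
companion of Kruskal–Wallis in SPSS-style workflows; it is hand-implemented
(no ready implementation among the package's dependencies) and
cross-checked in tests against a direct rank-sum oracle.

## Synthetic register

The generator's defaults are the study conditions: 7245 dispatches with an
exclusion probability of 829/7245 ≈ 11.4 %, so the analysis set
concentrates at ≈ 6416; category weights proportional to the 26 published
category sizes; per-category P(urgent dispatch) and P(urgent on scene |
dispatch stratum) from the published cells; the urgent stratum split into
A vs B at 341/2341 and the non-urgent into C vs D at 2260/4075 (the
published margins). The 263 dispatches belonging to the register's 29
unpublished rare categories are modelled as 29 small "Other" categories
whose shared conditional probabilities are the exact residual between the
overall crosstab and the published-category column sums (TP 59, FP 98,
TN 102, FN 4); with that closure the generator's expected overall confusion
cells equal the published ones, and the pipeline's cells are checked to lie
within 4 SD of that expectation at the study's scale.

Generation is latent-label-first: sample category, dispatch stratum and
target label, then materialise fields satisfying exactly one reference rule
for that combination, drawn uniformly over the applicable rules (per-rule
weights are not published; uniform is an explicit convention). With
probability 0.3 the paramedic assessment is documented and set to the
label — the documentation rate is a convention too, as only "voluntary" is
known. Rule-consistent vitals are sampled away from thresholds (e.g. SpO₂
uniform on [85, 92] for the bronchodilator rule) so float rounding can
never flip a label; threshold behaviour is tested with separate fixtures.
The defining contract — classification recovers the latent label for 100 %
of included records — is asserted on every generated register in the test
suite.

What the generator does *not* emulate: correlations between vitals and
category (a synthetic "Fall" can carry a CPR flag), call-to-scene timing,
geography, seasonality, and any real joint distribution of rule branches
within a confusion cell. Passing tests therefore validate the pipeline's
statistics and the classifier's logic, not claims about any real register
beyond the published marginal structure.

## Problem sizes and numerics

Tests and the acceptance script run the generator at the study's scale
(7245 dispatches) for aggregate checks. The category-comparison df check
runs at twice that scale: the smallest real category's expected size sits
exactly at the >50 threshold, so at 1× the eligible-category count is a
coin flip by design, while at 2× all 26 modelled categories clear the
threshold with many SDs of margin and the rare "Other" categories (≈ 18
expected each) stay well below it. Half-up decimal rounding is used at
render time because banker's rounding would print 2.5 % as 2. Degenerate
inputs fail loudly: empty analysis set, zero-marginal χ² tables, fewer than
two eligible categories, and non-injective codings all raise errors rather
than returning silent NaNs.
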