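# Methods

## Score evaluation

Each early warning score is a declarative list of items (`src/pewsval/
data/score_definitions.yaml`): a predicate over admission findings and a
nonnegative point value. Predicates support comparisons, category
membership, age-banded thresholds and boolean combinations; mutually
exclusive alternatives (e.g. the levels of a behaviour subscale) share a
group, and a definition is rejected at load time if its achievable
maximum — the sum over groups of the largest item points — exceeds the
score's declared range. The engine is data-driven so corrections to item
tables never touch code.

Item tables were reconstructed from the original score publications'
structure under the constraints of the cohort's data dictionary, and
carry four adaptations that such a cohort forces: the shock component
uses no blood pressure or pulse quality (not collected); its heart-rate
criterion is age-banded (>160/min under 12 months, >150/min from 12
months); capillary refill recorded as <2 s / 2–3 s / >3 s maps to +1 for
2–3 s and +2 for >3 s in Brighton PEWS; and the post-operative vomiting
item can never fire because surgical admissions are excluded. Because
some original sub-items have no counterpart in the data dictionary, the
adapted Brighton PEWS achieves at most 8 of its declared 0–13 range; all
other scores achieve their full range. Threshold conventions: "≥ x"
comparisons are closed on the printed value; hypoxaemia is strict
(SpO₂ < 90%).

Missing inputs follow a per-item policy: `score_zero` (default — an
unrecorded sign contributes nothing, and the affected item count is
reported) or `propagate_missing` (the total becomes missing and the
child drops out of analyses of that score). The default mirrors bedside
practice, where an unmeasured sign cannot add points.

Consciousness is a single 4-level AVPU-like field; scores defined on the
Blantyre Coma Scale are expressed as predicates on this field ("coma" =
responds to pain or unresponsive).

## Validation metrics

High risk is `score ≥ cutoff`. Weighted confusion counts are sums of
per-child population weights; sensitivity, specificity, PPV, NPV and the
likelihood ratios are computed from unrounded ratios, with PPV/NPV
flagged undefined (NaN) on an empty margin. All metrics are invariant to
rescaling the weights by any positive constant.

The weighted AUC is pairwise concordance (ties half credit), computed by
one sort and a sweep over distinct score levels; a brute-force O(n²)
oracle is kept in the package (`brute_force_auc`) for verification only.
Confidence intervals are percentile bootstrap over children (default
2000 replicates, resampled weights carried along, degenerate replicates
redrawn with a bounded retry), seeded and therefore deterministic; the
method is a design choice — DeLong-type variance is not implemented for
weighted data. Youden cutoffs scan every integer cutoff from 0 to
range_max + 1 and take the lowest argmax of J, favouring sensitivity on
ties. AUC bands: ≥0.8 excellent, [0.7, 0.8) acceptable/good, [0.5, 0.7)
poor, <0.5 not useful, applied to the unrounded AUC.

Analysis weighting follows the study design being emulated: full-cohort
analyses use population weights; within-stratum, per-site and per-age
analyses are unweighted (each level is its own reference population);
disease-restricted analyses inherit the full-cohort weights. The main
report evaluates every score on the full cohort so the weighted outcome
margins (tp+fn, tn+fp) are constant across rows; applicability
restrictions (RISC is defined for HIV-negative children) are enforced in
the designed-population analyses rather than the main table, matching
how the emulated validation presented its headline table. No
multiple-testing adjustment is applied; CIs are reported per row.

## Synthetic cohorts

The simulator emulates the sampling design of a multi-site paediatric
acute-illness cohort, not any real covariance structure. Defaults are
the study conditions: n = 3101 children aged 2–23 months at 9 sites,
exact-quota 2:1:2 enrolment over no/moderate/severe wasting strata,
stratum mortality (3.5%, 8.1%, 20.4%), syndrome prevalences drawn
independently (diarrhoea 55%, severe pneumonia 21%, malaria 14%, severe
anaemia 14% — they overlap, as multiple admission diagnoses do), and
~70% of deaths within the first two days. MUAC is drawn on a 0.1 cm grid
inside the assigned stratum's interval — strata partition the MUAC axis
with half-open boundaries (moderate is [11.5, 12.5) cm at ≥6 months,
[11.0, 12.0) below; oedema forces severe) — so stratum assignment
round-trips exactly.

Each child carries one latent severity z ~ N(0,1) plus a site shift
(default shifts spread over ±0.5 to make site analyses non-trivial).
Death is Bernoulli with probability expit(a_s + β·z), where β
(`severity_effect`, default 1.0) couples severity to death and the
per-stratum intercept a_s is solved numerically so the marginal stratum
mortality equals the configured rate for any β (without calibration the
logistic curvature would inflate mortality whenever β > 0). Every binary
sign is Bernoulli with a logit-linear severity term; SpO₂, heart rate,
respiratory rate and temperature are severity-shifted truncated normals
with age offsets; consciousness and capillary refill are ordinal cuts of
a noisy severity copy; weight-for-age is stratum-centred. Death day is
geometric with a severity-dependent rate, so the sickest children die
earliest — this is what produces better discrimination for day-2 than
day-30 mortality. Measured fields (vitals, WAZ, capillary refill) are
independently blanked at `missingness_rate` (default 2%).

Population weights are target-share / sample-share per stratum; the
target hospital population defaults to 0.80/0.10/0.10 across strata — a
plausible general admitted population, explicitly arbitrary because real
weighting targets for such designs are rarely published. Weighted
stratum shares reproduce the target exactly and the mean weight is 1.

Because signs depend on the same scalar severity that drives death,
every score is discriminative by construction and simulated AUCs
(~0.65–0.75) are not estimates of any real cohort's AUCs; passing tests
demonstrate the correctness of the pipeline's arithmetic and design
logic, not clinical performance. Real data differ in ways the simulator
deliberately omits: multi-dimensional illness physiology, site case-mix,
correlated syndromes, informative missingness and post-discharge
follow-up.

## Numerical and testing choices

Ties in scores get half concordance credit everywhere, making
AUC(s) + AUC(−s) = 1 exact for tie-free data. Equality comparisons on
MUAC boundaries are exact because generated MUAC lives on a 0.1 cm grid.
All randomness descends from explicit integer seeds; report bundles are
byte-reproducible given (cohort file, definitions file, seed), and
per-row bootstrap seeds are derived by hashing the base seed with the
row's identity so adding a subgroup never shifts another row's CI.

Problem sizes in the test suite are chosen to keep the full run around
half a minute: oracle equivalence uses 500 random instances (n ≤ 50);
simulator recovery uses n = 10⁴ with a 3-binomial-SE band; bootstrap
coverage uses 50 repetitions of n = 1500 cohorts (500 replicates each)
against a n = 10⁵ reference AUC with a ≥90% containment bound; the
probit-generator recovery check compares the empirical AUC at n = 10⁵
with the generator's probabilistic index obtained by numerical
integration, within 0.01.

## Known limitations

Item-level point values are reconstructions constrained by published
ranges, cutoffs and the documented adaptations — not transcriptions of
any study's supplementary tables; scores with laboratory components were
reduced to their clinical items. The simulator's single-severity model
cannot produce scores that disagree strongly with each other, so rank
differences between scores on synthetic data are weakly informative.
DeLong CIs, calibration analysis, score re-fitting and decision-curve
analysis are out of scope.
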