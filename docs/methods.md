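# Methods

## Kano classification and prioritization

Each of the 18 PR service attributes (8 dimensions: exercise ×3,
respiratory muscle training ×3, diet ×2, psychological ×2, education ×3,
oxygen therapy ×2, expectoration ×1, TCM-based therapy ×2) is probed with a
functional/dysfunctional question pair on the five-level scale *Like it,
Must-be, Neutral, Accept it, Dislike*. The 25 possible answer combinations
map deterministically onto the six Kano categories via the standard
evaluation grid (`kanopr.kano.EVALUATION_TABLE`); the grid is total, so
classification never fails on canonical levels.

**Final category.** Per attribute, categories are tallied over respondents
and the modal category wins. The tie-break order is fixed at
M > O > A > I > R > Q, following the Kano provision-priority ordering
(must-be qualities should be provided first, then one-dimensional, then
attractive). Ties are essentially absent in realistic tallies but the order
makes the assignment a total function.

**Coefficients.** SI = (A+O)/(A+O+M+I) and DSI = −(O+M)/(A+O+M+I).
Reverse and questionable answers are excluded from the denominator, as the
coefficient definition dictates; an attribute with no A/O/M/I answers gets a
flagged-undefined coefficient pair, and an attribute whose *modal* category
is R or Q is excluded from quadrant placement (this never occurs in the
reference data). The identity SI − |DSI| = (A−M)/(A+O+M+I) and the bounds
SI ∈ [0,1], DSI ∈ [−1,0] are property-tested.

**Quadrants.** The matrix graph plots |DSI| (x) against SI (y). The default
split is 0.5 on both axes — the conventional "important if above 0.5"
threshold; `KanoAnalyzer(split="mean")` uses per-axis cohort means instead,
a common alternative. A coefficient exactly equal to the split is *not*
"above" it (strict inequality), so the boundary is unambiguous.

**Known caveat.** On the reference tallies, the expectoration-guidance
attribute has SI = 139/237 ≈ 0.59. A published summary of the same analysis
quotes an SI range of 0.73–0.88 for the nine one-dimensional attributes;
that lower bound is inconsistent with the attribute's own printed counts
under the coefficient formula. The formula is authoritative here: the
package reports 0.59 and makes no attempt to match the quoted range minimum.
(One printed percentage — 22 answers rendered as 9.7 % — is similarly
ignored in favour of the integer counts, which sum to 237 in every row.)

## Missing data

A respondent with a missing half-pair on an attribute is excluded from that
attribute's tally only (per-attribute listwise deletion), so denominators
may vary by attribute. Covariates missing for a subgroup split exclude the
respondent from that split only. Psychometric blocks use listwise deletion
within the block.

## Subgroup comparison

Within each subgroup level the full Kano procedure is re-run; per attribute
the level × category table is tested with Pearson's χ² (no continuity
correction). R and Q columns are dropped before testing — they carry at
most one answer per attribute in data like the reference cohort and would
only destabilize the statistic; all-zero remaining columns are also dropped.
When any expected cell is below 5, the p-value falls back to Fisher's exact
test for 2×2 tables, otherwise to a seeded Monte-Carlo sample (default 2000
draws) of tables with the observed margins; the reported statistic is always
the Pearson χ². Three-level covariates (income, education) are tested as a
single omnibus table. The significance threshold is α = 0.05 two-sided with
no multiplicity correction across the 18 attributes — a deliberate mirror
of common practice in this survey literature, and a documented limitation:
with 7 specs × 18 attributes, a handful of false positives is expected.

An attribute is *divergent* when its final category differs across levels;
the scientifically interesting rows are divergent *and* significant.

## Psychometrics

Cronbach's α uses the variance-ratio form k/(k−1)·(1 − Σ var_item /
var_total). KMO is the overall measure: Σr²/(Σr²+Σp²) over off-diagonal
entries, with partial correlations from the scaled inverse correlation
(anti-image) matrix. Answer levels are coded Dislike = 1 … Like it = 5; α
depends on the coding only through equal spacing and KMO not at all (both
invariances are tested). Singular correlation matrices raise a dedicated
error rather than being silently regularized; the block report records NaN
for such a block.

## Intention workflow

The 1–5 intention score is treated as continuous in the primary model.
Candidate covariates are screened univariately (one-way ANOVA across the
five intention levels for quantitative variables; χ² with Fisher fallback
for categorical), then the survivors enter an OLS fit. Binary factors are
coded 0/1 (yes = 1); multi-level categoricals are one-hot encoded with the
first sorted level as reference; perceived-influence items keep their 1–5
scores. Diagnostics: Shapiro–Wilk p on residuals (delegated to SciPy),
Durbin–Watson, and per-predictor tolerance = 1 − R² of the auxiliary
regression of that predictor on the others, with VIF = 1/tolerance
(cross-checked in tests against an independent VIF routine). Rank-deficient
designs are rejected; fewer than 10 observations per predictor warns.

The proportional-odds logistic cross-check refits the same design with the
outcome ordinal; `significance_agreement` reports per-predictor
significance and sign agreement between the two fits. Suspected separation
(non-convergence or exploding coefficients) sets a flag instead of failing.

## Synthetic cohorts

The generator (`kanopr.simulate`) emulates the reference study conditions:

* **Kano answers** — per-attribute multinomial category propensities equal
  to the published tally proportions (N = 237 cohort); a drawn category is
  spread uniformly over its preimage in the evaluation grid, because
  published tallies constrain categories, not raw pairs. Attributes are
  sampled independently: the true inter-item dependence is unidentifiable
  from published summaries. Consequently synthetic cohorts have
  near-zero inter-item correlation, so reliability statistics (α, KMO) on
  synthetic data are structurally low — passing psychometric tests
  demonstrates correctness of the statistics, not the reliability of any
  real instrument.
* **Covariates** — independent margins matching the published cohort:
  region 156/81 Hangzhou/Quzhou, 78.5 % male, education 92/94/51, income
  48/122/67, stage 142/95 stable/acute, awareness 149/88, mMRC probabilities
  (0.04, 0.14, 0.595, 0.17, 0.055) reproducing the 43/194 grade split and
  the 59.5 % share of grade 2, age ≈ N(76.6, 10²) clipped to 45–97 (giving
  the published 104/133 under/over-75 split in expectation).
* **Intention** — linear latent score: intercept 2.13 plus the published
  coefficient vector (awareness 0.43, no-drinking 0.14, staff skills 0.44,
  knowledge promotion −0.17, transportation −0.10, family support 0.17) on
  0/1 indicators and 1–5 influence scores, Gaussian noise SD 0.8, then
  round-and-clip to 1–5. Influence-item distributions are skewed high for
  facilitator items (mean ≈ 4.3) and mid-scale for barrier items
  (mean ≈ 3.5), chosen once so the implied willingness share (intention ≥ 4)
  sits near the published 75 %. The pre-rounding score is always emitted as
  `intention_latent`: round-and-clip censoring attenuates OLS, so
  parameter-recovery checks regress on the latent scale; the clipped score
  is what the analysis pipeline consumes. An ordinal-logit generator
  (`kind="ordinal"`, default thresholds 2.0/3.0/3.7/5.0) serves the
  proportional-odds checks.
* **Subgroup shifts** — optional per-(spec level, attribute) propensity
  overrides. `awareness_shift_config()` reproduces the published
  aware/unaware pattern (six attributes one-dimensional for aware patients,
  indifferent for unaware) by solving A+O = SI, O+M = |DSI|, A+O+M+I = 1
  for each published coefficient pair, with the free must-be share set to
  0.03 (clipped into its feasible interval).

A fixed seed yields a byte-identical cohort. Non-response mechanisms beyond
MCAR, inter-attribute copulas and category life-cycle dynamics are out of
scope.

## Verification strategy and problem sizes

All grid examples, the published tallies, categories and coefficients are
exact desk-scale checks. Stochastic properties use seeded simulations sized
for stable verdicts: χ² type-I error over 2000 simulated two-group cohorts
of 120 per group with shared propensities (0.15/0.45/0.10/0.30 over A/O/M/I
— chosen without near-empty cells so the asymptotic test is actually
exercised), a power curve at 50/100/200 per group under a 0.2 O→I mass
shift, and OLS parameter recovery over 500 replicate cohorts of 237. The
large-N calibration round-trip uses 100 000 respondents; modal-category
stability at the study's own N = 237 is checked over 10 seeds (≥16/18
attributes matching in ≥9 seeds — attributes 4–6 sit on a 40.9 %/42.6 %
knife-edge and flip by design).

## Limitations

* Row-level data of the reference cohort are not redistributable; published
  data-dependent quantities (e.g. the functional-block α of 0.831, the
  Durbin–Watson of 1.824, the awareness coefficient 0.43 with SE 0.10, the
  per-attribute subgroup χ² values) are targets for *structure*, not unit
  tests: the pipeline reproduces them only given the original spreadsheet
  through the schema-mapping layer.
* Independence across attributes and covariates in the generator understates
  the correlation structure of real questionnaires.
* No multiplicity correction in subgroup testing (mirrored from field
  practice, flagged above).
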