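# kanopr

Kano-model demand analysis for pulmonary-rehabilitation (PR) services among
COPD patients — a tested, reusable implementation of the full questionnaire
analysis pipeline: response-pair classification, category tallying,
satisfaction/dissatisfaction coefficients, quadrant prioritization, subgroup
demand comparison, questionnaire psychometrics, and the
participation-intention regression workflow, plus a calibrated synthetic
cohort generator.

## The problem

Pulmonary rehabilitation (exercise training, breathing exercises, diet
guidance, psychological support, education, oxygen therapy, expectoration
guidance, TCM-based therapy) is effective for COPD but poorly taken up in
many settings. To target limited resources, providers need to know *which*
services patients actually demand, and which patient characteristics shift
those demands. The Kano model answers this from paired questionnaire items:
for each service attribute a *functional* question ("if provided, how would
you feel?") and a *dysfunctional* question ("if not provided, …?"), each on
the five-level scale *Like it / Must-be / Neutral / Accept it / Dislike*.

Every answer pair maps through the 5×5 Kano evaluation grid onto a quality
category: **A** attractive, **O** one-dimensional, **M** must-be,
**I** indifferent, **R** reverse, **Q** questionable. Per attribute the
modal category over respondents is the *final category* (ties broken
M > O > A > I > R > Q), and the customer-satisfaction coefficients are

```
SI  = (A + O) / (A + O + M + I)        # "better":  0 ≤ SI ≤ 1
DSI = −(O + M) / (A + O + M + I)       # "worse":  −1 ≤ DSI ≤ 0
```

Attributes are plotted with |DSI| on x and SI on y; those with both above
0.5 (upper-right quadrant) are the top-priority services. Demand differences
between subgroups (awareness, intention, mMRC dyspnea grade, age, income,
education, region) are tested with a Pearson χ² on the groups × categories
table (R/Q pooled out; Fisher/Monte-Carlo fallback for sparse tables). The
1–5 participation-intention score is analysed with a univariate screen
(ANOVA / χ²) followed by OLS with a diagnostic battery (Shapiro–Wilk,
Durbin–Watson, tolerance/VIF) and a proportional-odds cross-check.

The package ships the published summary tables of a 237-patient reference
cohort (Zhejiang, China) as worked-example inputs and calibration targets
(`kanopr.reference`).

## Worked example

```python
import kanopr as kp

# a synthetic cohort calibrated to the reference tallies
frame = kp.simulate_frame(n_respondents=237, seed=1)
analyzer = kp.KanoAnalyzer(split=0.5).fit(frame)
print(analyzer.summary_[["label", "final_category", "si", "dsi", "quadrant"]].head(8))
```

```
                                                  label final_category    si   dsi  quadrant
attribute_id
1             Provide upper limb exercise interventions              I  0.22 -0.19         3
2             Provide lower limb exercise interventions              O  0.74 -0.64         1
3               Provide systemic exercise interventions              I  0.40 -0.38         3
4                      Provide chest breathing training              O  0.57 -0.45         2
5                 Provide pursed lip breathing training              I  0.55 -0.43         2
6                  Provide abdominal breathing training              I  0.44 -0.36         3
7                         Inform about prohibited foods              O  0.86 -0.90         1
8             Inform about how to properly arrange diet              O  0.86 -0.88         1
```

Attribute 7 ("inform about prohibited foods") is one-dimensional with
SI = 0.86 and |DSI| = 0.90: satisfaction rises strongly when the service is
provided *and* falls strongly when it is withheld, so it lands in the
upper-right quadrant — provide it with top priority. Attributes 4 and 5 sit
near the published 40.9 % O vs 42.6 % I knife-edge, so their modal category
flips between simulated cohorts of this size — exactly the sampling
behaviour the tally margins imply.

Running directly on the published tallies reproduces the reference analysis
exactly — 9 one-dimensional and 9 indifferent attributes, maximum SI 0.88,
all nine O attributes above 0.5 on both axes:

```python
from kanopr.reference import REFERENCE_TALLIES
results = kp.results_from_counts(dict(REFERENCE_TALLIES), split=0.5)
nine_o = [r for r in results if r.final_category is kp.KanoCategory.ONE_DIMENSIONAL]
print(len(nine_o), max(round(r.coefficients.si, 2) for r in nine_o),
      sum(r.quadrant == 1 for r in nine_o))   # -> 9 0.88 9
```

There is also a CLI over the same library:

```bash
kanopr --seed 1 --out out/ simulate --n 237
kanopr --out out/ report out/survey.csv
```

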