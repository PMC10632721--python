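# fvgdr

Relative-validity analysis for the **fruit-and-vegetable component of the
Global Dietary Recommendation score (FV-GDR)**: a toolkit for researchers
who want to know whether a six-question yes/no diet quality questionnaire
(DQQ) can stand in for a quantitative 24-h recall (24hR) when monitoring
fruit and vegetable consumption at the population level.

## What it computes

Both assessment methods are reduced to six binary consumption indicators
per respondent-day, one for each GDR fruit-and-vegetable group — vitamin
A-rich vegetables, dark green leafy vegetables, other vegetables, vitamin
A-rich fruits, citrus, and other fruits. The questionnaire yields the
indicators directly; the recall yields them by mapping item-level gram
records into the six groups, counting a group only when some item reaches
15 g (with all-quantities and sentinel-item-only variants for sensitivity
analysis). The FV-GDR score is the number of groups consumed:

    FV-GDR = Σ_g 1{group g consumed},   0 ≤ FV-GDR ≤ 6

The validation battery then compares the two methods:

* **prevalence differences** per group (DQQ − 24hR, in percentage
  points), tested with a random-intercept linear mixed model and flagged
  *meaningful* when p < 0.05 **and** |difference| > 10 pp;
* **2×2 agreement**: percentage agreement ((a+d)/n)·100, type I
  (false-positive, b/n) and type II (false-negative, c/n) misreporting,
  and sensitivity d/(c+d) / specificity a/(a+b) of the questionnaire
  against the recall reference;
* a **paired Wilcoxon signed-rank test** on the total-score difference;
* **standardized slopes β_st** of total F&V gram intake on each method's
  score from random-intercept linear mixed models (REML), a
  correlation-like effect size that respects the two-days-per-respondent
  clustering;
* a **dependent overlapping correlation comparison** — Zou's confidence
  interval for r(intake, 24hR-score) − r(intake, DQQ-score) and the
  Hittner et al. z statistic;
* an **adherence cut-off analysis**: the half-integer score threshold
  maximizing Youden J for classifying intake ≥ 400 g/day (the WHO
  recommendation), plus the share of observations at/above an integer
  cut-off per method.

Because real dual-method field data of this kind are rarely shareable,
the package ships a first-class synthetic-data generator
(`fvgdr.simulate`) producing paired questionnaire/recall tables with
known ground truth: within-person correlation across the two recall
days, group-specific consumption prevalences, lognormal item amounts,
configurable small-portion, false-positive and false-negative reporting
mechanisms, and a sentinel-coverage dial.

## Worked example

```python
from fvgdr import FVGDRValidation, scenario_presets, simulate

cfg = scenario_presets()["ibadan_like"]   # small-portion over-reporting scenario
res = FVGDRValidation.from_simulation(simulate(cfg)).fit()
print(res.summary())
```

```
FV-GDR validation: questionnaire (DQQ) vs. 24-h recall reference
========================================================================
matched observations: 1200 (600 respondents)

      group p_dqq p_r24h diff_pp   p_value  meaningful    a   b  c    d agreement_pct fp_pct fn_pct sensitivity specificity
     va_veg  94.2   59.3    34.9 1.02e-120        True   63 425  6  706          64.1   35.4    0.5        0.99        0.13
       dglv  82.7   81.1     1.6      0.22       False  183  44 25  948          94.2    3.7    2.1        0.97        0.81
  other_veg  86.7   85.9     0.8     0.533       False  134  35 26 1005          94.9    2.9    2.2        0.97        0.79
   va_fruit  17.7   16.4     1.3     0.312       False  984  19  4  193          98.1    1.6    0.3        0.98        0.98
     citrus  12.2   10.7     1.6     0.132       False 1051  21  2  126          98.1    1.8    0.2        0.98        0.98
other_fruit  41.8   41.2     0.5     0.746       False  688  17 11  484          97.7    1.4    0.9        0.98        0.98

Wilcoxon paired (DQQ - 24hR score): W = 12095.5, p = 1.12e-72, median diff = 0
beta_st intake ~ 24hR score: 0.73 (95% CI 0.69, 0.77); sigma_u = 0.22, sigma_e = 0.65
beta_st intake ~ DQQ score: 0.64 (95% CI 0.60, 0.69); sigma_u = 0.22, sigma_e = 0.73
correlations: r(intake, 24hR) = 0.73, r(intake, DQQ) = 0.65, r(24hR, DQQ) = 0.81
dependent-correlation comparison: z = 6.80, p = 1.04e-11, 95% CI for r12 - r13 (0.06, 0.11)
optimal DQQ-score cut-off for >= 400.0 g/d: 3.5 (Youden J = 0.47); % at/above cut-off 3: DQQ 81.8, 24hR 65.1
optimal 24hR-score cut-off for >= 400.0 g/d: 2.5 (Youden J = 0.50); % at/above cut-off 3: DQQ 81.8, 24hR 65.1
```

Reading the output: in this scenario the questionnaire over-reports
vitamin A-rich vegetables by 34.9 percentage points (the only difference
that is both significant and larger than 10 pp), almost entirely through
type I misreporting (35.4% of observations), because the group is mostly
eaten in sub-15 g portions that the recall's 15 g rule excludes.
Agreement is high (94–98%) everywhere else, and the questionnaire-based
score still tracks true gram intake (β_st = 0.64) — just less tightly
than the recall-based score (β_st = 0.73), a difference the
dependent-correlation test calls real (z = 6.80).

The same battery runs from the shell on any CSV triplet:

```bash
fvgdr simulate --preset hanoi_like --out data/
fvgdr validate --dqq data/dqq.csv --recall data/recall.csv \
               --mapping data/mapping.csv --out report/ --cutoff 3
fvgdr score    --dqq data/dqq.csv --recall data/recall.csv \
               --mapping data/mapping.csv --out scores.csv
```

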