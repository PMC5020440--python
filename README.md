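# ranknorms

Rank-based social-norms analysis of intoxication judgments.

## The problem

When people drink in busy night-time environments, how do they judge how
drunk they are — and how risky their drinking is?  The intuitive account
says judgments track *absolute* intoxication (breath alcohol
concentration, BrAC, in μg alcohol / 100 ml breath).  The rank-based
social-norms account, rooted in decision-by-sampling theory, says
judgments instead track where one's BrAC *ranks* among the people in the
same environment: a drinker surrounded by drunker people feels safer at
the same absolute BrAC.

`ranknorms` implements that analysis as a tested, reusable pipeline for
researchers in alcohol epidemiology and behavioural public health:

1. **Reference groups.**  Survey respondents are partitioned into
   gender × location strata; everyone with a recorded BrAC — including
   zero readings — counts as a comparator.
2. **Rank statistics.**  For a respondent whose group of size *n*
   contains `below` members with strictly lower BrAC and `above` with
   strictly higher:

   - relative rank  `R = below / (n − 1)` ∈ [0, 1]
   - weighted rank  `SR(η) = 1/2 + (below − η·above) / (2·(below + η·above))`

   The comparison-bias parameter η asymmetrically weights upward versus
   downward comparisons; `SR(1) = R` exactly.  η < 1 means judgments are
   dominated by more-sober comparators, η > 1 by more-intoxicated ones.
3. **The regression ladder.**  For each 1–10 judgment outcome, OLS
   models: (1) outcome ~ BrAC; (2) outcome ~ R; (3) outcome ~ BrAC + R +
   (BrAC − group mean); (4) Model 3 plus session duration, an
   after-11pm flag, gender, FAST score and age.  Reported per term:
   *b*, standardized β, normal-theory 95 % CI, significance band; per
   model: R² and variance inflation factors `VIF_i = 1/(1 − R²_i)`.
   Under a rank mechanism, Model 3 keeps the rank coefficient and kills
   the BrAC coefficient.
4. **η estimation.**  A grid search over η ∈ {0.01, 0.02, …, 5.00}
   refits `outcome ~ SR(η)` at every grid point and selects the η that
   maximizes R².
5. **Synthetic cohorts.**  Because the underlying street-survey data are
   not publicly deposited, a seeded generator emulates them: ~1,862
   respondents in 8 gender × location groups with truncated-normal BrAC
   calibrated to the study's per-gender moments, plus a judgment
   subsample whose ratings are produced by a configurable rank /
   weighted-rank / absolute mechanism.  Every downstream stage is
   testable end-to-end without any download.

## Worked example

```python
import ranknorms as rn

pool = rn.generate_pool(rn.CohortConfig(), seed=7)
mech = rn.JudgementMechanism("rank", intercept=2.78, slope=3.42, noise_sd=1.75)
judgements = rn.generate_judgements(pool, mech, n_sub=400, seed=8,
                                    outcomes=("judge_drunk",))
frame = rn.build_analysis_frame(judgements)
fit = rn.fit_model(frame, rn.ModelSpec(3, "judge_drunk"))
print(fit.params[["b", "ci_low", "ci_high", "stars"]].round(3))
```

prints (judgments here were *generated* from rank alone):

```
                           b  ci_low  ci_high stars
const                  2.767   1.403    4.130   ***
brac                  -0.002  -0.024    0.019
rank                   3.747   1.934    5.560   ***
group_mean_distance   -0.000  -0.029    0.029
```

Joint adjustment attributes the effect correctly: the rank
coefficient's CI excludes zero (≈ the generating slope 3.42) while the
BrAC CI covers zero — even though BrAC alone (Model 1) would have looked
significant as a proxy for rank.  Scanning η on weighted-rank data
generated at η\* = 0.70 with noise at R² = 0.22 recovers

```
best eta = 0.78 with R2 = 0.232      # single 2,000-judgment replicate
```

with the median over 20 replicates landing within ±0.10 of 0.70.

The same pipeline runs from the shell:

```bash
ranknorms run-all --seed 42 --out-dir out/     # simulate + analyze + report
ranknorms simulate --seed 42 --out survey.csv  # just the synthetic survey
ranknorms scan-eta --in survey.csv --out eta.json
```

`run-all` writes `survey.csv`, `report.json` (all fits, diagnostics, η
profiles, provenance) and `report.txt` (rendered tables).  The
`examples/` directory contains one narrative script per capability.

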