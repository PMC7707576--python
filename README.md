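# lexirate

Rates of lexical evolution from phylogenetically independent sister
pairs, with Bayesian Poisson regression on sociodemographic predictors.

## The problem

Languages gain and lose basic-vocabulary words over time, and the pace
of this turnover varies enormously between lineages. Comparative claims
about *why* — population size, geographical isolation, conflict — are
confounded by shared ancestry: closely related languages resemble each
other in both their rates and their social settings. The sister-pairs
design controls for this. Each pair of tip languages that are each
other's closest relatives is an independent replicate of the same
natural experiment: one ancestral language split in two, and the two
daughters evolved under (possibly) different conditions.

`lexirate` implements that design end to end for cognate-coded
wordlists of the kind used in Austronesian comparative linguistics
(210 basic-vocabulary concepts, cognate sets assigned within concepts):

1. **Sister-pair extraction** — parse a time-calibrated Newick tree,
   take every cherry, filter on posterior support (default ≥ 0.80) and
   divergence depth, and drop pairs on an explicit reject list.
2. **Gain/loss counting** — for each concept attested in both sisters,
   a cognate set present in exactly one sister is classified by a
   Dollo-style rule: if it recurs in any background language at the
   same concept it was inherited and the other sister *lost* it;
   if it occurs nowhere else in the family it is a *gain* on the branch
   holding it. Turnover = gains + losses. Identified loan words are
   removed first, so shared cognates reflect descent, not borrowing.
3. **Predictor transforms** — log population size, log(km + 1) distance
   to the nearest landmass inhabited by a different culture, and three
   reversed 4-point conflict ordinals, each z-standardised; with VIF,
   Pearson-correlation and χ² independence diagnostics.
4. **Bayesian Poisson regression** — per response y ∈ {gains, losses,
   turnover},

   ```
   y_i ~ Poisson(μ_i)
   log(μ_i) = α + β₁·logPopulation + β₂·ConflictWithinCommunities
            + β₃·Isolation + β₄·ConflictWithinCultures
            + β₅·ConflictBetweenCultures
   α ~ Normal(0, 10),   β_k ~ Normal(0, 2)
   ```

   sampled with three MCMC chains of 10,000 iterations (2,000 warmup;
   24,000 pooled draws), summarised by posterior medians and 90% HPDIs,
   and compared across a 10-model set (null, full, five singles, three
   additive combinations) by WAIC weights and Bayesian R².
5. **Synthetic studies** — a generator that simulates covariates,
   draws per-pair counts from the log-linear model, and constructs a
   cognate matrix realizing those counts *exactly*, so every stage of
   the pipeline is verifiable without external data.

## Worked example

Simulate a 25-pair study with strong effects (isolation speeds change,
between-culture conflict slows it), recount events from the cognate
matrix, and fit the full gains model:

```python
import numpy as np
from lexirate import (SimTruth, SamplerConfig, ModelSpec, PREDICTORS,
                      simulate_study, tabulate_events, fit_poisson_glm, bayes_r2)

truth = SimTruth(beta_gain=(0.5, 0.2, 0.9, -0.3, -0.5), n_pairs=25, seed=1)
study = simulate_study(truth)

events = tabulate_events(study.pairs, study.matrix)
print(events[["pair", "gains", "losses", "turnover"]].head(3).to_string(index=False))

ps = fit_poisson_glm(study.design, ModelSpec("gains", PREDICTORS, name="full"),
                     SamplerConfig(seed=1))
print(ps.summary().round(2).to_string())
print("Bayesian R2 (median):", round(float(np.median(bayes_r2(ps))), 2))
```

prints

```
           pair  gains  losses  turnover
lang000|lang001     18      25        43
lang002|lang003     20      24        44
lang004|lang005     22      23        45
                                median    sd  hpdi_90%_lower  hpdi_90%_upper  rhat      ess
parameter
alpha                             2.78  0.05            2.70            2.87   1.0  1207.41
beta_logPopulation                0.41  0.11            0.24            0.60   1.0  1271.74
beta_ConflictWithinCommunities    0.22  0.08            0.09            0.35   1.0  1218.04
beta_Isolation                    0.83  0.08            0.70            0.97   1.0  1057.42
beta_ConflictWithinCultures      -0.33  0.07           -0.44           -0.22   1.0  1272.81
beta_ConflictBetweenCultures     -0.46  0.10           -0.61           -0.30   1.0  1396.88
Bayesian R2 (median): 0.91
```

Each β is the multiplicative effect (on the log scale) of one standard
deviation of that predictor on the gain rate: here the posterior
recovers the generating coefficients (0.5, 0.2, 0.9, −0.3, −0.5), every
HPDI excluding zero has the right sign, and split-Rhat of 1.00 with
effective sample sizes above 1,000 indicates the chains mixed.

The same pipeline runs from the shell on files:

```sh
lexirate simulate --out study/ --seed 1 --beta-gain 0.5,0.2,0.9,-0.3,-0.5
lexirate extract-pairs --tree study/tree.nwk --out study/pairs.csv --min-support 0.8
lexirate count --wordlist study/wordlist.csv --pairs study/pairs.csv --out study/events.csv
lexirate fit --events study/events.csv --predictors study/predictors.csv \
             --pairs study/pairs.csv --out study/fit --seed 1
```

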