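# Methods

## Sister-pair design

The unit of analysis is a *cherry*: two tip languages whose most recent
common ancestor is shared with no other sampled language. Because every
retained pair hangs from a distinct node, differences within a pair
accumulated independently of every other pair, which removes the
phylogenetic pseudo-replication that affects cross-language regressions.
Pairs are read off a rooted, time-calibrated Newick tree (branch lengths
in years; internal-node labels taken as posterior supports, auto-rescaled
from percentages when values exceed 1). Filtering defaults: support
≥ 0.80; an optional maximum divergence so that pairs spanning essentially
the whole tree — opposite ends of the family rather than close
relatives — are excluded; and an explicit reject list for pairs whose
classification is contradicted by external reference sources, since that
judgement cannot be automated. Nodes with more than two children are
never cherries by default; an opt-in flag pairs the tip children of a
polytomy greedily for sensitivity work. Both the single-branch
divergence time and the two-branch path length are carried, because
either may be wanted as an exposure measure.

## Counting gains and losses

For each concept attested in **both** sisters, every cognate set present
in exactly one sister is one event:

* present in ≥ 1 background language *at the same concept* → the set was
  inherited, so the sister lacking it lost the word (**loss**, charged
  to that sister);
* present nowhere else in the family at that concept → an innovation on
  the branch of the sister holding it (**gain**).

Sets present in both or absent from both sisters are uninformative.
Synonym cells contribute one event per qualifying cognate set. Turnover
is gains + losses, exactly.

Three choices deserve justification:

* **Missingness vs. absence.** A (language, concept) cell with no entry
  at all is missing data and the concept is skipped for that pair; a
  cell emptied by loan filtering stays "attested but empty" and can
  witness a loss. Conflating the two would count collection gaps as
  losses.
* **Concept-scoped background matching.** A background occurrence of a
  cognate set under a different concept does not rescue a loss, because
  cognacy here requires a common meaning, not just a common etymon. A
  flag relaxes this to family-wide matching for sensitivity analysis.
* **Loans.** Loan-flagged entries are removed before counting. A
  borrowed word is neither an innovation on the branch nor evidence of
  inheritance, and including loans makes sisters look more similar than
  their vertical histories warrant.

The counter is verified against an independent brute-force classifier
that enumerates the full universe of (concept, cognate set) combinations
and applies the rules literally, on 1,000 random matrices.

## Predictors

Per language: population size (log), distance in km to the nearest
landmass inhabited by a different culture (log(x + 1), because 0 km —
a different culture on the same island — is a legal value and the offset
maps it to 0 while preserving order), and three 4-point conflict
ordinals coded 1 = most frequent conflict. The ordinals are reversed as
v → 5 − v so that larger always means more conflict; any strictly
decreasing map gives the same standardised column, so the canonical
choice is immaterial. All five columns are z-standardised (n − 1
convention, matching R's `scale()`) over exactly the analysis languages,
after transforms and before pair aggregation, so effect sizes are
comparable across predictors and across pairing modes.

**Pairing modes.** The response is a per-pair count while predictors are
per-language, and the aggregation is genuinely open. Three modes are
first-class:

* `pair_mean` (default): predictor = mean of the two sisters' values,
  response = pair total. The mean is the only symmetric,
  orientation-free level summary, and it matches a model formula written
  in predictor *levels*.
* `two_row`: one row per language with its own branch counts — uses the
  per-branch information but gives two half-informative rows per pair.
* `signed_contrast` (experimental): within-pair differences with a
  deterministic orientation on a focal predictor.

Diagnostics: variance inflation factors from regressing each
standardised predictor on the others (all predictors continuous after
standardisation, so the generalised VIF reduces to plain VIF; flagged at
≥ 2, infinite under exact collinearity rather than crashing), pairwise
Pearson correlations with p-values from the t transform, and a Pearson
χ² independence test on cross-tabulations with a low-expected-count
warning.

## Bayesian Poisson regression

Per response y ∈ {gains, losses, turnover}:
y_i ~ Poisson(μ_i), log μ_i = α + βᵀx_i, with α ~ Normal(0, 10) and
β_k ~ Normal(0, 2). The β prior is weakly regularising on the log-rate
scale: a one-SD predictor shift multiplying the rate by e^±4 is already
extreme. An optional log-exposure offset (e.g. log pair path length) is
available but off by default, keeping fidelity to the count-scale
formulation; rate-per-year analyses are a sensitivity option.

**Sampling.** Default backend: adaptive random-walk Metropolis. The
proposal covariance is the Laplace approximation at the posterior mode
(damped Newton iterations on the log posterior, which for this model is
smooth and unimodal), scaled by 2.38/√d with a per-chain scalar step
size tuned toward 30% acceptance during warmup only — the post-warmup
kernel is fixed, so the chain targets the exact posterior. Three chains
of 10,000 iterations with 2,000 warmup give 24,000 pooled draws; for the
6-parameter full model at n = 25 this yields effective sample sizes
above ~1,000 in a few seconds. An `emcee` ensemble backend sits behind
the same contract and is used in the tests as an independent
cross-check; the intercept-only posterior is additionally checked
against grid quadrature. Convergence gate: split-Rhat ≤ 1.01 and
ESS ≥ 400 per parameter (via arviz); failures annotate the result and
make the CLI exit non-zero unless explicitly allowed — never silent.

**Summaries.** Point estimate = posterior median. Interval = 90% HPDI,
computed as the narrowest window of ⌈0.9·n⌉ consecutive order
statistics, ties broken toward the lowest start. "Significance" means
the 90% HPDI excludes zero.

**Model comparison.** WAIC on the deviance scale,
−2(lppd − p_waic), with lppd from log-sum-exp over draws and
p_waic the S−1 sample variance of pointwise log-likelihoods; the
standard error comes from the spread of pointwise deviance
contributions. Weights are exp(−Δ/2), normalised. The 10-model set per
response is: null, full, the five single-predictor models, and three
additive combinations. The combination set is configurable; the default
(demography+geography, the three conflict scales, demography+conflict)
was chosen so that all ten models are distinct — a "demography-only"
combination would duplicate the single-predictor population model and
split WAIC weight between two identical models.

**Bayesian R².** Per posterior draw,
R² = Var_i(μ_i) / (Var_i(μ_i) + mean_i(μ_i)): explained variance over
explained plus the Poisson model-implied residual variance
(variance = mean). Always in [0, 1); exactly 0 for the null model.

## Synthetic studies

The generator emulates the three real inputs:

* **Covariates**: log-normal population with median 26,485 speakers
  (log-sd 1.3); isolation distance as a 30% point mass at 0 km
  (same-island neighbours) mixed with a log-normal (median 40 km,
  log-sd 1.5, implying a mean around 120 km); conflict ordinals
  categorical with probabilities (0.2, 0.3, 0.3, 0.2).
* **Counts**: gains and losses drawn independently per pair from the
  log-linear model with separate intercepts and coefficient vectors
  (defaults α_gain = log 15, α_loss = log 25, matching event counts in
  the tens per pair over 210 concepts); turnover is their sum exactly.
  Events split between branches by a fair coin, since the default
  analysis uses pair totals. Linear predictors above 20 are refused
  rather than overflowing.
* **Cognate matrix**: a constructive realization. Every pair gets a
  shared filler set per concept (uninformative), each background
  language its own filler; each gain is a globally unique set in one
  sister; each loss a unique set in the other sister plus one of the
  pair's four dedicated background languages. This makes
  `tabulate_events(realize(E)) = E` an exact identity, tested per event.
  At most one gain and one loss per concept per sister keeps matrices
  realistic, so per-branch counts are capped at the concept count.

What the generator does **not** emulate: realistic tree shapes beyond
cherries-plus-outgroups, sound change or semantic drift, borrowing
dynamics (loans appear only as pre-flagged rows for filter tests),
correlated covariates, or rate variation within a branch. Passing
recovery tests therefore show that the estimator chain is correct and
calibrated *under the model*, not that the model is adequate for any
particular empirical dataset.

## Validation under study conditions

At the study scale (25 pairs, 210 concepts, default sampler), over 20
replicates: posterior medians fall within two posterior SDs of truth
for ≥ 90% of parameters; coefficients of magnitude ≥ 0.5 exclude zero
from the 90% HPDI in a majority of replicates; under a zero-effect
truth the 90% HPDIs cover zero at roughly the nominal rate (binomial
band 80–98% over 100 intervals); and when data are generated from the
full model with strong effects the full model takes essentially all
WAIC weight. `scripts/acceptance.py` recomputes all of these.

## Numerical and degenerate-input choices

* Ultrametricity is checked with relative tolerance 10⁻⁶ of tree depth
  and reported as a warning, not an error.
* Pairs with no recorded node support pass the support filter (unknown,
  not bad); this is logged.
* With zero observations the fit returns the prior (used as a prior
  predictive check in tests); an empty background set is an error
  because losses would be undetectable.
* WAIC requires ≥ 2 draws; HPDI requires ≥ 10 draws; the HPDI mass must
  be in (0, 1).
* Seed-fixed runs are bit-reproducible for a given backend and
  configuration; model fits inside a comparison derive distinct
  sub-seeds from the configured seed.

## Limitations

The counting rules inherit the Dollo assumption that a cognate set
arises once: chance resemblance or undetected borrowing violates it.
Background coverage bounds loss detection — a loss is only visible if
some background language retains the set, so sparse background sampling
deflates losses relative to gains. The per-pair counts are treated as
exchangeable given covariates; divergence-time heterogeneity is only
addressed via the optional exposure offset. And the pairing-mode
ambiguity is real: coefficients are comparable across modes only
qualitatively, which is why the mode is an explicit, recorded
configuration choice.
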