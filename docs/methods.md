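# Methods

## Estimand and model

The package targets the causal life-course effect of two-period psychosocial
adversity on a continuous ageing outcome. Exposures are either the
cumulative adversity score per period (0–3, the sum of three binary types:
substance abuse by someone close, material deprivation, pooled
physical/sexual abuse) or a single type. The outcome model is

    E(Y | Child, Adult) = β₀ + δ (w·Child + (1−w)·Adult),   w ∈ [0, 1].

δ is a single signed effect per unit of weighted adversity and (w, 1−w) are
simplex period weights. This parameterization encodes the unidirectionality
assumption — both periods push the outcome in the same direction — which is
what makes the period "contributions" interpretable as nonnegative shares.
Causal interpretation additionally requires consistency, no interference,
positivity, and exchangeability given measured confounders.

Confounding is handled by weighting rather than regression adjustment,
because the adulthood exposure has *intermediate confounders* (own education
and household income) that are themselves affected by childhood adversity:
adjusting for them in an outcome regression would block part of the effect
and open collider paths.

## Weights

Two time-ordered propensity models are fitted per exposure: childhood on
baseline confounders (sex, age, parental education, nativity), adulthood on
baseline confounders + intermediates + the childhood exposure history.
Cumulative scores use multinomial logistic models (a proportional-odds
structure is deliberately not assumed); binary types use logistic models.
Fits are unpenalized scikit-learn logistic regressions on standardized
designs; non-convergence raises a named error rather than returning silently
biased probabilities.

Weights are stabilized by default (numerators: marginal P(A₁), conditional
P(A₂|A₁)), so the total IPTW has mean ≈ 1 and the pseudo-population keeps
the original size. Predicted probabilities at or below a floor (default
1e−6) raise a positivity error listing the offending subjects; weights are
never silently clipped. Truncation at configurable percentiles is available
but off by default. The final analysis weight is IPTW × survey sampling
weight. Diagnostics report mean/min/max/99th percentile and the Kish
effective sample size (Σw)²/Σw².

Two sensitivity covariate sets extend the baseline conditioning set: with
six blood cell-type proportions (one dropped as redundant on the simplex),
or with smoking status (two dummies).

## Weighted finite population Bayesian bootstrap

Credible intervals must reflect that the analysis weights are part of the
design. Each WFPBB replicate (default 200):

1. Normalizes the weights to sum to the population size N and reforms the
   finite target population with a weighted Pólya urn: unit i starts with
   mass wᵢ − 1 (itself is already observed) and the urn adds (N − n)/n mass
   per draw over the N − n imputation draws. The sequential urn is sampled
   through its exact Dirichlet-multinomial representation, which is the same
   distribution at O(n) cost. Units with weight below one get urn mass zero
   (they represent no one beyond themselves).
2. Draws a simple random sample of the original size n (without replacement;
   with replacement available) from the reformed population. Everyone in the
   replicate has weight one, so an unweighted Bayesian model is valid on it.

When the supplied weights are genuine survey expansion weights (sum at least
`pop_factor`·n), N = round(Σw). Relative weights — e.g. stabilized IPTW
times unit-mean sampling weights, whose sum is ≈ n — would make the urn
degenerate (no units to impute), so they are rescaled to a nominal
population of `pop_factor`·n (default 10), which approximates the
infinite-population weighted Bayesian bootstrap. Under either choice the
expected replicate mean equals the Hájek weighted mean exactly, which the
tests verify by Monte Carlo.

## Posterior computation

Priors: β₀, δ ~ Normal(0, 100²); w ~ Uniform(0,1) (Dirichlet(1,1) on the
simplex); σ² ~ Inverse-Gamma(10⁻³, 10⁻³). The inverse-gamma prior on σ² is
chosen for exact Gibbs conjugacy; at the sample sizes involved (hundreds and
up) it is numerically indistinguishable from other weak priors on σ.

The sampler alternates (i) an exact bivariate-normal draw of (β₀, δ) given
(w, σ²), (ii) an inverse-gamma draw of σ², and (iii) a Metropolis step for
w: a random walk on the logit scale with Robbins–Monro step-size adaptation
during warm-up (target acceptance 0.4), mixed with a 10% rate of
independence proposals from the uniform prior so the chain still traverses
[0, 1] when δ ≈ 0 leaves w weakly identified. Because the likelihood
depends on the data only through ten scalar sufficient statistics, each
iteration is O(1) in n and a 200-replicate × 1000-draw analysis takes
seconds. Defaults: 1000 warm-up + 1000 retained draws per replicate.
Effective sample sizes (Geyer initial-positive-sequence estimator) and the
w acceptance rate are recorded per replicate; low ESS emits a warning and is
stored in the diagnostics, never dropped. With w fixed (a degenerate prior)
the sampler reduces to conjugate Bayesian linear regression, which the tests
check against the closed form.

Replicate posteriors are pooled by equal-draw concatenation — a mixture
posterior whose spread contains both within-replicate uncertainty and
between-replicate (weight/sampling) variability. Summaries are posterior
means, percentile 95% CrIs, PP = P(δ > 0), and the adulthood weight as
1 − w.

## Mediation

The pathway hypothesis is probed by mediating childhood adversity (A)
through adulthood adversity (M), with an A×M interaction by default.
Because the mediator–outcome confounders are exposure-induced, natural
effects are unidentified and the randomized interventional analogues are
estimated: the mediator is drawn from its interventional distribution
P(M | A = a). With a 4-level mediator both effects are closed-form sums:

    rNDE = Σₘ [E(Y|a,m) − E(Y|a*,m)] P(M=m|a*)
    rNIE = Σₘ  E(Y|a,m) [P(M=m|a) − P(M=m|a*)]
    TE   = rNDE + rNIE   (exactly, every call)

E(Y|A,M) is a weighted linear model using the full final weight (both
exposure and mediator deconfounded). P(M|A) is a saturated weighted
multinomial — weighted frequencies within exposure level — weighted by the
**childhood IPTW × sampling weight only**. This asymmetry is deliberate: the
interventional distribution is the population law of M given A once A is
deconfounded; including the mediator's own IPTW would re-impose the crude
(confounded) A–M association through its stabilization numerator, and in a
severed-path benchmark produces an asymptotic rNIE bias of ≈ 0.09 outcome
units that the correct weighting removes.

The default contrast is a one-unit increase of the childhood score (a* = 0
vs a = 1), configurable. CIs are percentile bootstrap over subjects
(default 500 replicates) with all weights re-estimated inside each
replicate, so weight-estimation uncertainty enters the interval. Degenerate
resamples (a vanished exposure/mediator level, propensity separation) are
skipped and counted, with a warning above a 5% skip rate.

## Compatibility scoring and verdict

Five reference points on the weight simplex encode the non-pathway
hypotheses: critical childhood (1,0), critical adulthood (0,1), accumulation
(0.5,0.5), sensitive childhood (0.67,0.33), sensitive adulthood (0.33,0.67).
For each posterior draw, ED to a reference is the planar Euclidean distance,
which on the simplex reduces exactly to √2·|w − ref_child|; the per-reference
posterior mean and 95% CrI are reported and the smallest posterior-mean ED
names the most compatible reference, with ties broken toward accumulation as
the most parsimonious. The overall verdict is *pathway* iff the rNIE 95%
bootstrap CI excludes zero ("rNIE ≠ 0" operationalized as interval
exclusion); otherwise the smallest-ED reference. Both the ED winner and the
pathway flag are always reported, so either reading of a result is
auditable.

## MSM cross-check

A weighted linear regression of the outcome on (Child, Adult) with the final
weights estimates period effects whose sum is the additive life-course
effect; when both share a sign, βᵢ/Σβ are implied period weights comparable
to the Bayesian posterior weights (flagged undefined otherwise, since the
Bayesian model excludes opposite-sign periods by assumption). HC1 sandwich
SEs are reported alongside subject-level bootstrap CIs with weight
re-estimation. Agreement with the Bayesian δ is expected (and tested) under
strong signal; implied-weight disagreement under weak signal is expected
behavior, not an error.

## Synthetic cohort generator

The generator emulates the structure of a two-visit US Hispanic/Latino
cohort with psychosocial assessment and blood DNA methylation, following
the causal ordering baseline confounders → childhood adversity →
intermediates → adulthood adversity → outcome. Defaults: female 61.4%,
US-born 18.6%, parental education ≥ high school 55.3%, own education 63.1%,
income ≥ $30k 27.9%, age ~ Normal(50.5, 12.91²) truncated to [18, 95];
deprivation prevalence 54.2% (childhood) and 52.0% (adulthood); substance
abuse by someone close 35%/25% and pooled abuse 30%/12% (adult abuse
deliberately uncommon), chosen once as plausible mid-range values where no
tabulated figure was available. Smoking (never/former/current
61.8/21.3/16.9%) and six Dirichlet cell-type proportions are optional
columns for the sensitivity covariate sets.

Exposure and intermediate models are logistic; each adulthood type carries a
log-odds carryover from its childhood counterpart (the chained-exposure
dial). Logistic intercepts are calibrated by root-finding so realized
marginal prevalences match their targets given the drawn upstream variables
— prevalence targets are exact study conditions, not tendencies. The
outcome adds baseline-confounder terms and Gaussian noise to the weighted
life-course mean; intermediates affect the outcome only if explicitly
switched on, keeping the marginal ground truth (β₀, δ, w) transparent.
Sampling weights are log-normal with unit mean and configurable dispersion
(default σ = 0.4). A DunedinPACE factory calibrates the intercept and
residual SD analytically to a marginal mean of 1.08 and SD of 0.12 years
per calendar year.

Two benchmark factories fix the scenarios used throughout testing:
`pathway_scenario` (carryover 2.0 per type, δ = 2, w = 0.15) and
`accumulation_scenario` (carryover 0, the child→intermediate path also
severed — the accumulation hypothesis posits independent exposure windows —
δ = 2, w = 0.5).

What the generator does *not* emulate: DNA methylation arrays, probes or
clock construction; multistage survey design (weights are i.i.d.
log-normal, not design-based); missing data (the pipeline rejects rather
than imputes); measurement error in self-reported adversity; more than two
exposure periods. Passing tests therefore demonstrate the statistical
machinery under the assumed causal structure, not robustness to the
measurement problems of real cohort data.

## Numerical choices and problem sizes

Tests and the acceptance script run the full method at reduced problem
sizes chosen to keep the whole suite in minutes while leaving Monte-Carlo
error far below the tested tolerances: typically n = 2000 subjects, 50 WFPBB
replicates × 1000 draws for recovery/coverage checks, 20 simulated cohorts
for coverage and verdict-stability rates, 10,000–50,000 subjects for
closed-form and regression oracles, and 150–200 bootstrap replicates inside
pipeline runs. The analysis defaults (200 replicates, 1000+1000 draws, 500
bootstrap) follow the analysis protocol and remain the shipped defaults.

Degenerate inputs: identical child and adult columns leave w unidentified
(the posterior returns the prior — correct, if uninformative); an all-zero
exposure column makes the MSM design singular and raises; non-finite
outcomes are rejected before sampling. RSS is floored at tiny positive
values against catastrophic cancellation in the sufficient-statistics form.

## Known limitations

* Two periods only; no nonlinear exposure–outcome links.
* The ED comparison treats (0.67, 0.33) as "sensitive period" literally;
  other sensible encodings of "one period contributes more" exist.
* Percentile CrIs of the pooled mixture posterior have no exact frequentist
  guarantee; coverage is checked empirically at the simulated conditions.
* The bootstrap skips degenerate resamples, which slightly biases CIs when
  exposure levels are very rare.
* Propensity models are parametric (multinomial/logistic); residual
  confounding from their misspecification propagates to all stages, as in
  any IPTW analysis.
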