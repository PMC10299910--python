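# Methods

## Model

The analysis object is a recursive system of regression equations over
observed variables, indexed by a DAG. Each endogenous node has a family and
link chosen by its measurement type:

* Gaussian, identity link — infant birth weight (kg), child BMI-for-age
  z-score;
* Bernoulli, logit link — breastfeeding ≥ 6 months, rapid weight gain (RWG)
  in infancy, overweight status.

Because the system is recursive, all nodes are observed, and equation error
terms are independent, the joint likelihood factorizes into per-equation
likelihoods; equation-wise maximum likelihood therefore maximizes the joint
likelihood (a property the test suite verifies against a brute-force joint
optimizer on small instances). The default structure
(`standard_pathways`) is:

```
maternal BMI → {birth weight, breastfeeding, RWG, outcome}
birth weight → {breastfeeding, RWG, outcome}
breastfeeding → {RWG, outcome}
RWG → outcome
```

with the outcome either child BMI z-score (Gaussian) or overweight status
(logit), fitted as two separate systems sharing the harmonized table. The
temporal ordering breastfeeding → RWG is fixed in the default structure;
arbitrary DAGs can be supplied via `PathSpec`.

**Covariates.** Cohort indicators (k−1 dummies), maternal age, child sex and
intervention allocation enter every equation. Assessment ages are placed
where they time a measurement: infancy age in the RWG equation, childhood
age in the outcome equation. The rationale is that an assessment age is only
meaningful for the measurement it dates; a switch (`ages_everywhere=True`)
puts both ages in every equation as a sensitivity probe. Maternal education
(tertiary vs not) is an optional covariate appended to every equation;
cohorts lacking the column drop out of the complete-case set when it is
active. Intervention allocation is always a covariate, never a moderator.

**Moderation.** `test_moderation` refits each equation with
moderator-by-parent interaction terms, reports a likelihood-ratio test per
equation, and issues a Bonferroni-adjusted global verdict (α/k across the k
equations).

## Effect decomposition

Effects live on the *estimation scale*: linear coefficients into Gaussian
nodes, log-odds into logit nodes. The direct effect is the exposure→outcome
edge coefficient; an indirect effect is a product of edge coefficients along
a mediated path; products that cross scales (e.g. a log-odds coefficient
into a binary mediator times that mediator's coefficient on a continuous
outcome) are taken as-is, which reproduces derived-coefficient computation
on the fitted parameters. For binary mediators such cross-scale products
are approximations to counterfactual (natural) mediation effects — adequate
under a rare-outcome/moderate-effect regime — and this package deliberately
implements the product-method estimand, not a counterfactual estimator.

Three "via M" grouping conventions are implemented:

* `single` (default): IE via M is the two-edge product
  β_{X→M}·β_{M→Y}, and TE = DE + Σ_M IE_M. This is the convention under
  which the reference decomposition tables this package mirrors are
  internally consistent (e.g. log 0.14 × 0.72 ≈ −1.42 for the birth-weight
  → RWG → BMI-z indirect effect, and 0.57 − 1.42 + 0.01 ≈ −0.84 for the
  total), so it is the reporting default.
* `first`: all simple paths partitioned by their first mediator. TE then
  equals the full sum over simple paths, which on an all-Gaussian DAG
  coincides with the covariance-algebra total effect (I−B)⁻¹ — verified
  against that matrix oracle in the tests.
* `containing`: every path containing M contributes to M's group. Groups
  overlap (shared paths are counted in several groups), so they do not sum
  to TE − DE; the result is marked non-additive.

For the additive conventions the conservation identity TE = DE + Σ IE is
asserted to machine precision on every decomposition, and re-asserted
independently at the reporting layer. Odds-ratio reporting applies exp(·)
to estimation-scale values; significance is always judged on the estimation
scale (CI excluding 0), equivalent to the OR interval excluding 1.

**Mediation classification** (per mediator, from significance flags):
*full* — IE significant, DE not, TE significant; *partial* — IE and DE
significant with the same sign; *suppression* (inconsistent mediation) — IE
and DE significant with opposite signs; *none* — IE not significant (or no
other pattern applies).

## Estimation kernel

Gaussian equations are solved by least squares; the reported log-likelihood
uses the ML variance estimate (divisor n) so that likelihood-ratio tests,
AIC (−2ℓ + 2p) and BIC (−2ℓ + p·ln n) are likelihood-consistent, while
standard errors use the unbiased variance (divisor n − p). The Gaussian
parameter count includes the variance.

Logit equations are maximized by iteratively reweighted least squares
(Newton scoring) with step-halving, which makes the log-likelihood
non-decreasing across iterations — asserted inside the engine. Convergence:
max |score| < 1e−8, or relative log-likelihood change < 1e−10. Rank
deficiency raises an error naming the collinear columns; constant design
columns (e.g. cohort dummies on a single-cohort table) are dropped with a
logged notice rather than an error. Separation — coefficients diverging
past |β| > 15 with a non-vanishing gradient — raises an explicit error
rather than returning silently divergent output; a small ridge penalty
(1e−4 on non-intercept coefficients) is available as a logged fallback for
bootstrap replicates only, where resampling occasionally induces
quasi-separation in small strata.

## Bootstrap

Resampling draws individual records with replacement, **stratified by
cohort** (each cohort resampled to its own size), preserving the group
sizes the cohort fixed effects condition on; an unstratified mode exists
behind a flag. Each replicate re-runs estimation and decomposition; only
equations feeding the requested effects are refitted (coefficients are
identical to a full refit — the skipped equations cannot change them).
Failed replicates (separation, rank loss) are skipped and counted; more
than 10% failures aborts the run. One master seed drives counter-based
per-replicate streams (`numpy` `SeedSequence.spawn`), so results are
bit-for-bit reproducible and independent of chunking.

Intervals (default level 0.95, default B = 1000):

* **bias-corrected percentile** (primary): z₀ = Φ⁻¹(share of replicates
  below the point estimate, ties counted half), bounds at the
  Φ(2z₀ ± z_α) percentiles. Percentiles are interpolated linearly at the
  Efron k/(B+1) plotting positions (numpy `method="weibull"`), the
  standard convention for bootstrap percentile-type intervals; the default
  type-7 interpolation clips the tails at moderate B and measurably
  undercovers at B = 200. No jackknife acceleration is applied.
* **normal-based**: point ± z_α·SD(replicates), SD with divisor B_eff − 1.

With all replicates identical the BC interval degenerates to a point with a
warning; fewer than 100 replicates is an error.

## Synthetic cohort generator

The generator emulates seven pooled cohorts (total n = 3572 by default; a
`scale` factor shrinks every cohort for reduced experiments). Sampling
follows the DAG in topological order. Per cohort: maternal BMI is a
truncated normal (floor 15 kg/m²; the overweight-only pregnancy-trial
cohort is floored at 25 kg/m², reproducing its 0% normal-weight
composition); maternal age and assessment ages are normal (assessment-age
SDs of zero are allowed — several cohorts measured at one fixed age); sex,
intervention and education are Bernoulli draws from the cohort profile; the
one observational cohort is constant "control". Birth weight and BMI
z-score are Gaussian with residual SDs 0.5 kg and 1.0 (taken from the
descriptive SDs of the profiles); their intercepts are set so the cohort
means match the profiles. Binary nodes are Bernoulli-logit draws whose
per-cohort intercepts are *calibrated by root-finding* (bisection-type
`brentq`, tolerance 1e−6 on the prevalence) so simulated marginal
prevalences hit the profile targets — the reference analysis reports CIs,
not residual scales or intercepts, so these are calibration decisions of
this package, not published facts.

Edge coefficients default to the published pooled point estimates (stored
in `data/default_fixture.yaml`, not hard-coded), including the
non-significant ones at their printed values (the maternal BMI → RWG direct
effect is exactly 0 on the log-odds scale, printed OR 1.00). Overweight is
generated from its own logistic equation rather than by thresholding the
generated BMI z-score, because the two outcomes are estimated as separate
systems downstream (a thresholding mode exists for realism experiments).
In `growth-curves` mode the generator emits weight-for-age z-score pairs
whose difference falls strictly above/below 0.67 according to the drawn RWG
flag, and breastfeeding months consistent with the ≥ 6-month flag, so the
harmonization layer can be exercised end to end. An optional MCAR injector
exercises the complete-case filter; missingness is otherwise off.

**What passing tests show — and don't.** The generator reproduces the
reference marginals and path coefficients under the model's own assumptions
(correct link functions, independent errors, homogeneous effects across
cohorts, no unmeasured confounding, MCAR missingness at worst). Recovery
tests therefore validate the *estimation and decomposition machinery*, not
the causal claims: real cohort data bring measurement error, informative
missingness, cohort-varying effects and confounding that the generator
deliberately does not emulate.

## Harmonization conventions

RWG: weight-for-age z-change > 0.67, strict (a change of exactly 0.67 is
not RWG). Breastfeeding: ≥ 6 months, inclusive. Overweight: BMI at or above
the age/sex cutpoint, inclusive, with the cutpoint linearly interpolated in
age between tabulated rows; the cutoff table is caller-supplied (IOTF
tables are licensed content and the flag is preferentially consumed
precomputed). All thresholds are keyword-overridable. The same 0.67 rule is
applied at any infancy assessment age (0.6–1.1 y across the default
profiles). When a shipped flag and its raw columns are both present,
pooling re-derives the flag and treats a mismatch as an error rather than
silently preferring either. Missing-data policy is complete-case only — no
imputation — with dropped rows accounted per cohort and per variable.

## Sensitivity analyses

Leave-one-cohort-out refits the full system k times; every sign change
versus the pooled run is recorded, but the global "all same direction"
verdict weighs only effects that are significant in the pooled run or have
|estimate| ≥ 0.05 on the estimation scale (the 2-decimal reporting
resolution): the sign of an effect indistinguishable from zero is sampling
noise, not cohort heterogeneity. Timing subsets re-run the pipeline on
cohorts selected by per-cohort mean assessment age (presets: infancy ≥ 1 y;
childhood 3–4 y, i.e. mean < 4.5 y; childhood 5 y).

## Problem sizes used in the checked experiments

Recovery experiments average 20 full-size draws (n = 3572). Mediation
classification rates use 50 seeds with B = 200 bootstrap replicates.
Interval coverage uses 200 reduced experiments (cohorts scaled to a pooled
n ≈ 800, B = 200) — sizes chosen so the checks are informative while the
whole suite stays inexpensive. The measured 95% BC coverage at those sizes
is at the lower edge of its acceptance band, consistent with the known
small-B behaviour of percentile-type intervals.

## Known limitations

No latent variables, correlated errors, multilevel/random effects,
survey weights or robust/clustered standard errors (cohort structure is
handled by fixed effects only). No counterfactual mediation estimands or
exposure–mediator interaction decompositions. The product method's
cross-scale products are non-collapsible-scale approximations for binary
mediators. Bootstrap intervals are unadjusted for multiplicity across
effects. WHO z-score computation is out of scope (z-scores are consumed,
not computed).
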