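# Methods

## Model and estimands

The package works with a binary exposure $A$, binary outcome $Y$, baseline
covariates $C$ (not affected by the exposure) and mediators $M^1,\dots,M^K$
assumed to lie on separate causal pathways that are d-separated given $A$
and $C$. Counterfactuals are defined in a nonparametric structural
equations model with independent errors (NPSEM-IE): every variable is a
deterministic function of its parents and an independent exogenous noise,
and interventions are evaluated by substitution with the noise shared
across worlds. Cross-world quantities such as $Y_{A,M_0^k}$ (outcome under
the natural exposure but the mediator value it would have taken without
exposure) are therefore well defined.

Three readings of the pathway-specific PAF — interventional (mediator drawn
afresh from its eliminated-exposure distribution given covariates),
mechanistic (the individual's own counterfactual mediator) and separable
(a component of the exposure acting only through the mediator set to zero)
— share one identification formula,

$$\mathrm{PS\text{-}PAF}_k \;=\; \frac{P(Y=1) - E_{A,C}\,E_{M^k|A=0,C}\,P(Y=1\mid A,C,M^k)}{P(Y=1)},$$

so a single estimation routine serves all three; which interpretation is
licensed depends on which identifiability conditions the analyst accepts.
The simulator verifies the equivalence to $10^{-12}$ on d-separated
discrete models, and reports the (nonzero) gaps when one mediator is a
parent of another — that post-treatment-confounding setting is outside the
supported class, and the estimators refuse it with an explicit error rather
than returning biased numbers.

## Estimation

All estimators are plug-ins of the form
$[\sum_i w_i Y_i - \sum_i w_i \hat q_i] / \sum_i w_i Y_i$ with estimand-specific
counterfactual predictions $\hat q_i$:

- **PS-PAF, continuous mediator**: $\hat q_i$ evaluates the outcome model at
  the observed exposure with the mediator replaced by
  $\hat M^k_i = M^k_i - A_i(\hat E[M^k|1,C_i]-\hat E[M^k|0,C_i])$. Because
  the whole per-record distribution is shifted (not just a mean plugged in),
  this is consistent whenever the exposure acts as a location shift on the
  mediator. For *binary* mediators the shifted values leave the support and
  the estimator is consistent only when the outcome model is linear in the
  mediator on the probability scale; the default for discrete mediators is
  therefore the level-sum estimator below, with the mean-shift route kept as
  a diagnostic.
- **PS-PAF, discrete mediator**: $\hat q_i = \sum_m \hat P(M^k{=}m\mid
  A{=}0, C_i)\, \hat P(Y{=}1 \mid A_i, C_i, M^k{=}m)$ over the declared
  levels.
- **Direct PAF**: outcome model evaluated at $A=0$ with mediators at their
  observed values (all mediators, or one for the single-mediator variant).
- **Total PAF**: g-formula standardization through the joint outcome model
  at $A=0$ with every continuous mediator mean-shifted and every discrete
  mediator integrated over its fitted $A=0$ level distribution (mediators
  independent given $A,C$ under d-separation). A reduced-model route
  ($Y \sim A + C$) exists for comparison, but the joint route is the default
  so total, direct and indirect estimates share one fitted model.
- **Indirect PAF**: total minus single-mediator direct, as pure arithmetic;
  additivity is a floating-point identity, never a numerical coincidence.
- **Impact fraction**: the PS-PAF plug-in with a caller-supplied
  post-intervention mediator distribution (per-record shifted values or
  level probabilities) in place of the $A=0$ distribution.

With a single joint outcome model $P(Y=1|A,C,M^1..M^K)$, the PS-PAF for
mediator $k$ holds the other mediators at their observed values; under
d-separation this equals the single-mediator formula, and the package
asserts that reduction in its tests.

PS-PAFs use each record's *observed* exposure (the outer expectation is over
the joint law of $A$ and $C$); $A=0$ substitution happens only for direct
and total estimands.

## Study designs and weights

Cohort and cross-sectional data get unit weights. Case-control data get
$w=1$ for cases and $w=(1/\pi-1)/r$ for controls, where $\pi$ is the
(externally known) disease prevalence and $1:r$ the matching ratio; when
$r$ is not supplied it defaults to the realized control:case ratio of the
analyzed sample. With exactly $r$ controls per case the weighted case
fraction reproduces $\pi$ identically. Weights enter both model fitting
(frequency-style likelihood weights — the default, switchable to
averaging-only) and the estimator averages. Model-based standard errors
from weighted fits are never reported; the bootstrap is the sole inference
route, so the frequency/variance weight distinction has no consequence.

## Nuisance models

The outcome model is a weighted logistic regression (statsmodels GLM).
Identity and log links exist but are flagged experimental: their
predictions can leave $(0,1)$ and are clipped to
$[10^{-12}, 1-10^{-12}]$ with a logged warning. Continuous mediator models
are weighted least squares for $E[M^k|A,C]$; binary mediators use weighted
logistic regression and mediators with three or more levels a multinomial
logistic model (scikit-learn, unpenalized), with predictions mapped back to
the declared level order and checked to sum to one within $10^{-10}$.

Formulas are term lists rather than a formula language: plain columns,
`":"`-joined products, indicator-coded categoricals (reference = first
level in sorted order, for reproducibility) and natural cubic splines. The
spline basis is the restricted truncated-power construction (cubic between
knots, linear beyond the boundary), with boundary knots at the observed
min/max and interior knots at evenly spaced quantiles of the *weighted*
empirical distribution, so that case-control weights inform knot placement;
5 df is the conventional choice for flexible continuous-mediator terms in
the outcome model. Basis construction is deterministic given data and df.
Rank-deficient designs fail with the collinear columns named; perfect
separation and non-convergence raise estimation errors rather than warnings.

Every converged weighted logistic fit satisfies the intercept score
equation $\sum_i w_i(Y_i - \hat p_i) = 0$ (checked to $10^{-6}$ relative).
This identity is what makes the estimators exactly null-calibrated: when
the fitted mediator model shows no exposure effect, the PS-PAF numerator
collapses to the score equation and the estimate is zero to within solver
tolerance.

## Bootstrap inference

Standard errors are bootstrap SDs over replicates that resample records —
stratified by case status for case-control designs, preserving the case and
control counts exactly — recompute design weights from $(\pi, r)$, and
refit every nuisance model. Default 200 replicates; the 95% interval is
estimate $\pm\ 1.96\,\mathrm{SE}$, with percentile intervals available.
Per-replicate generators are spawned from the master seed by counter
(`SeedSequence(seed).spawn(n_boot)`), making runs bit-reproducible.
Replicates whose fits fail are dropped and counted; above 10% failures a
warning is attached, and if all fail an error is raised. Coverage of the
normal-approximation interval for the PS-PAF is checked empirically in the
test suite (100 cohorts of 5,000 records, 200 replicates each; at least 90
of 100 intervals must cover the exact value).

## The simulator and its oracles

`StructuralModel` holds topologically ordered nodes, each a finite-support
conditional distribution (inverse-CDF assignment of a uniform noise) or a
Gaussian (mean function of parents plus independent normal noise), with
declared covariate / exposure / mediator / outcome roles.

For all-discrete models, `enumerate_oracle` computes every functional
*exactly*: each node's uniform noise is partitioned at the cumulative
assignment probabilities arising across all parent configurations, which
makes the assignment constant on each atom in every counterfactual world;
summing over atom products (the outcome's own noise integrated
analytically) yields exact joint counterfactual probabilities. The
interventional functional uses the exact conditional law of $M_0^k$ given
each covariate configuration; the identification-formula value is assembled
independently from the observational joint table, so the equivalence check
compares genuinely distinct computations. Enumeration refuses models whose
noise-configuration count exceeds $10^7$.

For models with continuous nodes, `mc_oracle` samples shared noise
(default $10^6$ draws, seeded) and Rao-Blackwellizes the outcome (averaging
$P(Y=1\mid\text{parents})$ instead of sampled $Y$), reporting per-functional
Monte-Carlo SEs and delta-method SEs for the PAF ratios. Consistency tests
compare estimators against oracle values at three combined Monte-Carlo SEs,
with the estimator's own MC SE obtained by replication over independent
small cohorts scaled by root-$n$ — the oracle's Rao-Blackwellized SE alone
would understate estimator sampling noise.

## Synthetic study generator

`make_interstroke_like` emulates the structure of a large international
stroke case-control study: confounders age (Gaussian, mean 55, SD 10), sex,
three-level region and education, a diet score, stress, smoking and
alcohol; a binary physical-inactivity exposure (prevalence ≈ 0.3); a binary
hypertension mediator and Gaussian waist-hip-ratio and ApoB/ApoA-ratio
mediators, all shifted upward by exposure; and a rare stroke outcome whose
logistic intercept is calibrated by root-finding on a fixed internal
Monte-Carlo sample so the marginal yearly incidence hits 0.0035 (3.5 per
1000) — hence the 1:1 control weight of ≈ 284.7. Effect sizes are fixed,
plausible magnitudes (e.g. log-odds 0.45 for inactivity, 0.6 for
hypertension); an `exposure_effect` multiplier scales every structural
exposure effect, with 0 giving a global null for calibration checks. The
generator reproduces the *structure* of such a study — rare outcome,
case-control sampling, mixed mediator types, confounding — but not real
covariate correlations, measurement error, matching on covariates or
region-level heterogeneity, so passing tests demonstrate estimator
correctness under a correctly specified data-generating process, not
robustness to misspecification.

Randomized model grids: `random_logistic_sem` draws logistic SEMs with one
or two d-separated binary mediators and arbitrary-sign effects (used for
the identification-equivalence grid). `random_monotone_sem` draws
*additive-risk* SEMs in which every exposure and mediator effect is
risk-increasing and the exposure-mediator interaction in the outcome risk
is nonnegative, with parameters scaled so no probability is clipped. The
synergy restriction matters: the ordering "PS-PAF ≥ indirect PAF" is not a
theorem for monotone logistic models (the logistic link is concave at high
baseline risk, reversing the required supermodularity, and random logistic
grids do produce violations); it is provable on the additive-risk synergy
class, which formalizes the sufficient-component-cause picture of direct
and mediated mechanisms that must both be operational. The ordering and
"total PAF ≥ PS-PAF" are asserted over 110 random models from this class.
PS-PAFs across mediators plus the direct PAF typically sum to *more* than
the total PAF; the package treats this as expected behaviour, not an error.

## Numerical choices and limitations

- Problem sizes in the test suite: consistency at 200,000 records
  (canonical toy model) and 100,000 (Gaussian-mediator model);
  case-control fidelity at 2,000 cases; bootstrap coverage at 5,000
  records × 200 replicates × 100 cohorts; oracle grids of 110 models.
- Degenerate inputs fail fast: no cases, single exposure arm, empty
  simulated datasets, discrete mediator values outside declared levels,
  declared levels absent from data.
- Discrete level probabilities are validated to sum to 1 within
  $10^{-10}$; counterfactual-distribution containers enforce the same.
- Estimates are invariant to record order and to duplicating every record;
  both are tested.
- Not supported: mediators on the same causal pathway (post-treatment
  confounding), time-varying mediators and mediator trajectories,
  continuous exposures, multi-exposure joint PAFs, averaged sequential
  PS-PAF decompositions, doubly robust estimation, matched-pair conditional
  analyses, and survey weights beyond the case-control scheme.
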