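# Methods

`mctpref` implements a complete stated-preference pipeline for multi-cancer
tests (MCTs): experimental design, choice simulation, pooled mixed-logit and
hybrid latent-variable estimation, post-estimation transforms, and exhaustive
preference ranking. This note documents the models, the defaults and the
numerical choices, and what the synthetic-data experiments do and do not
establish.

## The descriptive system

A hypothetical MCT is described by seven attributes (level counts in
parentheses): positive predictive value PPV ∈ {20, 40, 60, 80}% (4), negative
predictive value NPV ∈ {96.0, 99.0, 99.5, 99.9}% (4), waiting time
{1 week, 1–2 weeks} (2), number of cancers covered {1, 5, 10, 25} (4), site
identification {yes, no} (2), sample form {blood, faecal, urine, breath} (4),
and early-stage detection {yes, no} (2). The Cartesian product spans
4·4·2·4·2·4·2 = 2048 profiles. Categorical attributes are dummy-coded against
the references PPV 80%, NPV 99.9%, 1 week, blood, site = no, early = no; the
number of cancers enters linearly per 10 cancers. A GP row therefore carries
13 main-effect columns.

Clinicians see all seven attributes. Because showing the public both accuracy
framings at once proved confusing in piloting, the public design is split:
each respondent is randomised to an arm that sees either PPV or NPV (six
attributes), and the pooled model recovers preferences for all seven. Hidden
attributes are encoded as structural zeros in both alternatives of a task,
which is algebraically identical to an arm-specific utility function with the
columns dropped; nothing is imputed.

## Experimental design

Designs contain 24 binary tasks split into two blocks of 12 (so each
respondent answers 12 choices) and are exactly level-balanced: each level of
each visible attribute appears the same number of times across the 48
alternative slots in every arm view.

The efficiency criterion is the Bayesian D-error, the mean over prior draws
of det(I(β))^(−1/K), where I is the binary-logit information matrix of the
dummy-coded design averaged per task (so duplicating tasks leaves the
criterion unchanged) and K the number of parameters. For split schemas the
criterion averages the two public arm views 50/50, each arm evaluated with
its own utility function — one design, two utility functions, averaged.
Priors are quasi-random normal draws (Sobol'; default 100) around a packaged
pilot-style mean with common variance 0.05.

The search is balanced-start coordinate exchange: a random exactly-balanced
start is repaired until no task has duplicate alternatives or an a-priori
dominated pair (one alternative weakly better on every monotone attribute —
PPV↑, NPV↑, cancers↑, site, early, waiting↓; form treated as non-monotone —
and strictly better somewhere), then pairwise level swaps between slots
(which preserve balance) are accepted whenever they reduce the D-error and
keep the constraints. The default is 200 sweeps; the tests and the
acceptance script use 8–10 sweeps, which already place the design far below
the median D-error of 100 random balanced designs. The search is
deterministic given the seed and can only improve on its starting design.
How such designs are generated varies across commercial tools; this
algorithm is the package's own choice.

## Synthetic data

The generator inverts the estimator's assumptions. Respondent n draws

  β_n = β_group + Σ_c δ_c·(z_nc − p_c) + τ·(LV_n − E[LV]) + σ∘ξ_n,  ξ_n ~ N(0, I),

one draw per respondent, common across their 12 tasks (panel structure).
Utilities are V = λ_cell · x'β_n plus independent standard Gumbel noise; the
argmax is recorded. Scale cells: GP ≡ 1, public PPV arm λ_public, public NPV
arm λ_public·λ_arm. The latent trait LV_n = γ'z_n + η_n (η standard normal)
also generates three binary indicators (screened, had cancer, tested; logit
links with intercepts α_k and loadings ζ_k) and a 0–16 symptom-recognition
count (ordered logit with 16 increasing cut points).

Two deliberate generator choices:

- **Centred heterogeneity.** Covariate and latent utility shifts are centred
  at their population means (prevalences p_c; E[LV] = γ'p), so the base
  coefficients remain population-average effects however much heterogeneity
  is switched on. An estimator using uncentred modifiers recovers the
  algebraically equivalent parameterisation (base coefficients offset by
  τ·E[LV]), which the recovery tests account for explicitly.
- **Fixture values.** The default truth transcribes published sample-level
  odds ratios for GP and public MCT preferences (e.g. GP PPV 60 vs 80 at
  ln 0.21, public early-stage at ln 2.61), with GP PPV coefficients exactly
  linear in PPV% (slope 0.078 per point) and GP NPV 96 at −2.528 so the GP
  NPV 99.9→96 trade equals 32.4 PPV points. These make synthetic runs
  qualitatively faithful; they are illustrative, not the study's estimates.
  Unreported quantities were fixed once at plausible values: random
  coefficients on the six PPV/NPV dummies with spread 0.5, λ_public = 0.9,
  λ_arm = 1.2, covariate prevalences near published sample descriptives.

What the generator does **not** emulate: quota screening, dropouts,
speeders, duplicate respondents, attribute non-attendance, or any deviation
from the logit error structure. Passing recovery tests therefore certify
that the estimators invert this data-generating process correctly — not that
real survey data satisfy it.

## Estimation

The pooled panel mixed logit maximises the simulated log likelihood

  LL = Σ_n w_n ln[ (1/R) Σ_r Π_t P_nt(β + σ∘ξ_nr) ],

with scrambled-Halton draws (default R = 500, per-respondent slices),
weights w_n = 0.5·N_total/N_group so the four-times-larger public sample does
not dominate, scale parameters estimated on the log scale (GP cell fixed at
1), and sample-dummy interactions δ giving the public coefficient shifts.
With all σ = 0 the likelihood reduces exactly to the multinomial logit.

Gradients are analytic throughout (validated against central finite
differences at 1e−6 relative); optimisation is L-BFGS from a zero start with
a fast MNL stage seeding the mixed stage (σ start 0.1), gradient-norm
tolerance 1e−5, at most 1000 iterations. The covariance is the
respondent-clustered sandwich A⁻¹BA⁻¹ — weighting invalidates the plain
inverse Hessian — with A from central finite differences of the analytic
gradient and B the outer product of per-respondent scores. Spread estimates
are unconstrained with |σ| interpretation.

Identification notes. Only scale ratios are identified, hence the GP
normalisation. With sample-dummy interactions on *every* attribute and no
mixing, λ_public rides an exact likelihood ridge (any λ is absorbed by
rescaled δ); it becomes identified through the shared mixing spreads in the
mixed model, which is how the recovery experiment estimates it. The
arm-scale λ_arm is identified from the relative magnitude of shared
coefficients across the two public arms even without mixing.

The interaction-refinement procedure fits the full model, then iteratively
removes the single interaction with the smallest |t| below the threshold
(default 1.96) and refits until every remaining interaction passes; main
effects are never removed, and the removal trail is recorded.

## The hybrid (ICLV) model

One latent trait — cancer knowledge and experience — links three blocks
estimated jointly by simulated ML: the structural equation LV = γ'z + η
(disturbance variance fixed at 1), measurement equations (logit for the
three binary indicators, ordered logit with 16 cut points for the symptom
count; cut points parameterised as a free first cut plus log-increments to
keep them increasing), and the choice model with utility shifts β_j + τ_j·LV
on selected attributes. The joint likelihood multiplies, inside the draw
average, the panel choice product and the measurement product per draw of
the latent disturbance (the last Halton dimension). At τ = ζ = 0 it
separates exactly (to numerical precision) into the mixed-logit and
closed-form Bernoulli/ordered-logit terms.

Sign identification: the likelihood is invariant to reflecting
(γ, ζ, τ) jointly; after convergence the solution is reflected so the
screening-indicator loading is positive (variances are unaffected; relevant
covariance rows/columns change sign). The trait has no structural intercept
— its location is absorbed by the measurement intercepts and base utility
coefficients, an invariance the tests verify numerically. Missing indicators
drop out of the affected measurement terms with a logged warning. Posterior
latent scores are computed by draw reweighting, E[LV_n | data] ≈
Σ_r J_nr LV_nr / Σ_r J_nr.

The ordered-category probability F(κ_hi − ζLV) − F(κ_lo − ζLV) is evaluated
in its complementary form when both arguments are positive; the naive
difference of CDFs near 1 loses six significant digits to cancellation and
visibly corrupts finite-difference gradient checks.

The exploratory factor analysis motivating the single trait is the classical
non-iterated one-factor principal-factor solution (squared multiple
correlation communalities, one eigen-decomposition). Iterating the
communalities is available but off by default: on data with *no* common
factor the principal-axis recursion is known to inflate a single spurious
communality, and the non-iterated pass already reconstructs one-factor
correlation structure to within 0.05 at n = 10 000. Pearson correlations are
used for the binary indicators (tetrachorics are not attempted), which
attenuates the variance share (~0.13 at the fixture) without affecting the
one-factor conclusion.

## Post-estimation

Odds ratios exponentiate coefficients; intervals are Krinsky–Robb
(percentiles over 10 000 seeded multivariate-normal parameter draws; a
numerically non-PSD covariance is repaired by eigenvalue clipping with a
warning). Because PPV is dummy-coded, a per-percentage-point slope is
defined as the least-squares line through (20, β₂₀), (40, β₄₀), (60, β₆₀),
(80, 0) — a fixed linear contrast, so its variance c'Σc is exact. This
definition is the package's own; it is justified by the observed start-point
invariance of the PPV trade-offs. The NPV→PPV marginal rate of substitution
is −Δβ_NPV / slope in PPV percentage points, with a delta-method interval
from the analytic gradient of the ratio; a slope with |t| < 1 flags the
result unstable (returned with a warning, not raised). MRS is invariant to
common rescaling of all utility parameters.

## Ranking

Predicted utilities use coefficient means (GP base; public base + δ) with
the group's scale (GP 1, public λ_public); a config switch to average over
mixing draws is deliberately out of scope for the headline numbers, which
rank at representative preferences. Off-grid numeric levels interpolate
linearly between adjacent level coefficients; values outside the level range
are clamped to the nearest level with a warning (the benchmark's >50 cancers
becomes 25). "Preferred in X% of cases" is the share of the 2048 enumerated
profiles whose binary-logit probability against the benchmark is below 0.5,
ties counted against the benchmark. The packaged benchmark is a
SYMPLIFY-like MCT (PPV 76%, NPV 98%, 1–2 weeks, identifies site, blood,
early-stage yes); FIT/PSA/CA125 comparator accuracies are illustrative
placeholders, as the original operating points are not public.

## Problem sizes used by the tests and the acceptance script

Recovery experiments run at 2000 public + 500 GP respondents (pooled mixed
logit, R = 500) and 2000 public respondents (ICLV, R = 500), each against a
3-standard-error criterion per parameter. Refinement size/power use 50
seeded replicates of 250 respondents with one candidate interaction. The
acceptance script reruns the full pipeline at the published sample sizes
(251 GP + 1005 public) with R = 300 for the pooled model and R = 200 for the
ICLV, and 8 coordinate-exchange sweeps for the design; these sizes are the
package's standard desk-scale configuration and are stated here so runs are
comparable.

## Known limitations

- Mixing distributions are normal only; no lognormal/triangular options.
- The mixed-logit simulated SEs inherit R-draw noise; spreads near zero are
  reported as |σ| without a boundary correction.
- The ICLV supports one latent trait; no latent-on-latent paths, no multiple
  factors.
- Ranking at coefficient means ignores preference heterogeneity; the
  draw-averaged alternative changes probabilities but rarely the ordering.
- Published benchmark-preferred fractions and odds ratios for real GP and
  public samples are reproducible only qualitatively here: they depend on
  coefficient estimates whose underlying survey data are not public, so the
  synthetic fixture can match their structure and signs but not their exact
  values.
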