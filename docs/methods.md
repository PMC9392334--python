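# Methods

## Trial structure and estimand

The package analyses a two-arm cluster-randomised noninferiority comparison:
schools are the unit of randomisation (1:1, stratified by region and
geolocation), teachers are nested in schools, and the outcome is the weekly
minutes of scheduled physical activity a teacher records in a logbook at
baseline and 12-month follow-up. The estimand for the primary outcome is the
baseline-adjusted between-arm difference at follow-up (adapted minus
original, minutes/week); for the component outcomes it is the between-arm
ratio of the baseline-to-follow-up change on the positive part, mapped onto
the minutes scale for the noninferiority decision (see below).

Noninferiority is declared against a margin Δ derived as
(1 − retained proportion) × (reference-trial lower confidence bound), signed
negative because more minutes are better. Both decision summaries are always
reported side by side and never collapsed into each other: the binary
interval rule (lower 95% credible bound ≥ Δ, boundary inclusive) and the
posterior probability P(difference ≥ Δ | data), computed as the exact
fraction of posterior draws on the non-inferior side. The component margins
(−8.25 / −1.58 / −0.95 minutes) are produced through the same derivation
with back-solved reference bounds at 50% retention, since only the margins
themselves are published inputs.

## Primary outcome model

Linear mixed model with a school random intercept and a baseline covariate:

    f_i = α + β g_i + γ b_i + u_{s(i)} + ε_i,   u_s ~ N(0, σ_u²),  ε_i ~ N(0, σ_e²)
    b_i ~ N(μ_b, σ_b²)                                  (baseline sub-model)

The baseline sub-model exists so that *both* missing baselines and missing
follow-ups can be imputed coherently: every missing outcome is a parameter,
redrawn each MCMC iteration from its full conditional (the follow-up's
posterior predictive, or the baseline's conditional given its sub-model and
the regression), i.e. one-step imputation. With no missing values the
imputation steps are empty and the model reduces exactly to the complete-data
fit. Teachers observed at only one timepoint stay in the analysis with the
other timepoint imputed (intention-to-treat with all available valid data).

Default priors (uninformative mode) are vague on the minutes scale:
N(0, 100²) on α, β, γ and μ_b; half-Normal(50) on σ_u, σ_e, σ_b. The
informative mode replaces the β prior with user-supplied Normal
hyperparameters; no defaults are invented for it. On trial-sized synthetic
data the two modes agree on β to well under a minute (the data dominate),
and the suite asserts this.

### Sampler

The LMM is fit by a blocked Gibbs scheme with exact conjugate conditionals
for all location parameters, school intercepts and imputed outcomes, and
univariate slice updates (stepping-out + shrinkage) for the three standard
deviations under their half-Normal priors. Two structural refinements matter
for mixing:

- (α, β) are drawn *jointly with the school intercepts integrated out*
  (partially collapsed Gibbs). The arm indicator is constant within school,
  so school means are sufficient and the update is a 2-parameter weighted
  Normal regression on per-school means with weights 1/(σ_e²/n_s + σ_u²).
  Without this, β and the intercepts are so strongly coupled that the
  centred sampler stalls when residual noise is small.
- γ is updated by a scalar conjugate draw given everything else (the
  baseline covariate varies within school, so no collapse is needed).

The chain layout defaults to the production configuration of 4 chains ×
(10 000 burn-in + 10 000 retained draws); tests and the acceptance script use
4 × (500 + 1000), which the coverage and calibration experiments show is
ample for this posterior (effective sample sizes in the hundreds to
thousands per chain set).

## Component outcome models

Each component (energisers, active lessons, PE — sport is a remainder, not a
modelled outcome) gets a longitudinal two-part model on complete cases:

    P(y = 0)  = logit⁻¹(a₀ + a₁ t + a₂ g + a₃ t·g + v_s)
    y > 0     ~ Gamma(k, mean μ),  log μ = c₀ + c₁ t + c₂ g + c₃ t·g + w_s

with independent school intercepts v_s ~ N(0, τ_v²) and w_s ~ N(0, τ_w²) in
the two parts — sharing one intercept across the logit and log scales would
be a stronger assumption than the model needs. No imputation is attempted in
these models; the longitudinal form (time + time-by-group) uses whatever
timepoints are observed. Priors: N(0, 100²) on all eight coefficients,
half-Normal(50) on τ_v, τ_w, half-Normal(10) on the shape k.

All conditionals are non-conjugate and are updated by univariate slice
sampling (coefficients, intercepts, log k with its Jacobian). Each part's
intercept SD additionally gets an interweaved non-centred update
(ancillarity–sufficiency interweaving): after the centred τ update, the
intercepts are rescaled jointly with τ on the non-centred parameterisation.
This breaks the funnel that otherwise traps τ near zero when clustering is
weak, and takes the τ diagnostics from R-hat ≈ 1.3–1.5 to ≈ 1.00.

Two post-processing maps produce reportable quantities:

- `exponentiate_interaction`: exp(c₃) draws — the between-group ratio of the
  change in the positive-part mean, the ratio-scale estimate shown in the
  results table.
- `hurdle_minutes_difference`: per draw, the expected minutes
  E[y] = (1 − π)·μ are evaluated at the four time-by-arm design cells with
  random intercepts at zero, and the difference-in-differences
  (adapted change − original change) is formed. This is this package's
  explicit construction for comparing hurdle outcomes to minutes-scale
  margins; a published analysis of this design does not spell out its
  mapping, so the construction is documented here rather than inferred.

## Generic sampling engine and diagnostics

`sample_posterior` accepts an arbitrary log-density and runs an adaptive
random-walk Metropolis sampler (global scale tuned to 23.4% acceptance,
per-coordinate widths from running posterior SDs, both frozen after
burn-in). Its contract is distributional correctness, validated in the test
suite against conjugate closed forms and an independent 2-D quadrature
oracle for a marginalised hierarchical model — not a particular transition
kernel. Gradient-based kernels would be preferable for high-dimensional
targets, but the two outcome models use the specialised Gibbs/slice schemes
above, and the generic engine only faces low-dimensional test densities.

Convergence diagnostics are the split-chain Gelman–Rubin statistic (clamped
at ≥ 1; constant chains report 1.0) and an autocorrelation-based effective
sample size using Geyer's initial monotone positive-pair truncation, capped
at the stored draw count. Runs with any parameter at R-hat > 1.05 or
ESS < 400 emit a prominent warning in the run log; results are still
produced, since diagnostics inform rather than censor. Draws export to a
long-format CSV for external inspection; arviz serves as an independent
cross-check of both diagnostics in the tests.

## Variance ratio (Bayesian ICC analogue)

The clustering summary is, per posterior draw, the proportion
(V_marginal − V_conditional) / V_marginal, where both variances are
*simulated* posterior-predictive outcome variances over the analysis design:
marginal re-draws the school effects from N(0, σ_u²) (for the hurdle model,
both parts' intercepts), conditional holds them at their posterior-drawn
values so only residual-level variation remains. The two replicates share
common random numbers at the residual level, which has two deliberate
consequences: a model with σ_u = 0 yields exactly zero (the replicates
coincide), and weak clustering can produce *negative* per-draw values and
interval bounds — matching how such ratios are reported in practice. The
literal marginal/conditional quotient is carried alongside for verbose
output. The analytic ratio σ_u²/(σ_u² + σ_e²) is the large-sample limit of
the per-draw summary, and the tests verify ≈ 0.5 when σ_u = σ_e.

## Synthetic-trial generator

The generator's defaults *are* the study conditions: 24 schools per arm,
4–7 teachers per school (≈ 265 teachers), baseline total activity
N(126, 46²) minutes/week, a follow-up gain of 36 minutes, a true arm effect
of −7.5 minutes, baseline slope 0.25, school SD 16 and residual SD 34
(giving a follow-up clustering proportion near 0.17), follow-up missingness
30% and baseline missingness 5% (completely at random — the weakest
mechanism consistent with an imputation model that conditions on arm and
baseline only), and an invalid-record rate of 0.125 *per school* (about 6 of
48 schools receive one inflated >250-minute follow-up record, mirroring
school-level exclusion tallies). Component hurdle parameters are calibrated
to the emulated trial's marginal moments (e.g. energisers: zero probability
0.60 at baseline, 0.13 at follow-up, positive-part mean 45, shape 1.2).

Totals and components must satisfy two different laws at once — a Normal
total-activity model and hurdle-shaped components — so components are drawn
first, a sport/other remainder absorbs the gap up to the Normal total, and
in the rare case the components overshoot the target total they are rescaled
into it. The recorded total therefore follows the Normal cluster model
*exactly* (which is what makes the coverage and calibration experiments
clean), at the price of a small (<3%) downward distortion of component
marginal means in overshooting records. The generator does not emulate:
informative missingness, teacher-level covariate effects, day-level
resolution, or baseline clustering (the between-school variance enters at
follow-up only, matching the analysis model; the emulated trial does not
report a baseline variance decomposition to calibrate against). Passing
tests therefore demonstrate correctness of the machinery under these
conditions, not robustness to, e.g., informatively missing logbooks.

## Validity filter

A record is invalid when its weekly total exceeds 250 minutes; exactly 250
is valid ("no more than 250" read inclusively — source descriptions of this
rule conflict at the boundary, so both the threshold and its inclusivity are
exposed as arguments). Records whose components are all missing pass through
as missing-outcome, not invalid; totals are computed over observed
components only. Exclusion operates on records (teacher-timepoints): a
teacher with an invalid follow-up keeps their baseline and re-enters the
model with follow-up imputed, and a school leaves the analysis only when all
its records are invalid or missing. The flow summary reports both tallies —
schools free of any invalid record, and schools contributing at least one
analysable teacher.

## Cost-minimisation

Ledger items are strategy-coded amounts in 2019 AUD; "shared" items are
apportioned equally across the arm's schools. Research and development costs
are excluded by never being ledger items. Point estimates are exact
arithmetic (per-school values rounded to whole AUD only for reporting);
uncertainty comes from a non-parametric bootstrap (default 1000 replicates)
resampling *schools* within arm — the costing unit and the natural
resampling unit for per-school summaries. The packaged ledger is a
constructed synthetic stand-in (the real ledger is not deposited): it
reproduces the published per-school strategy costs ($287 staff session
unique to the original arm; $484 champion training, $86 ongoing support,
$85 equipment pack in both arms) and closes the gap to the published arm
totals ($25 375 / $16 421) with an explicit per-arm balancing item covering
non-itemised salaries and distribution. Because the published "35% more
schools for a fixed budget" figure numerically equals the per-school cost
*reduction* (373/1057) rather than the schools-per-budget increase
(1057/684 − 1 ≈ 55%), both quantities are computed by distinct, explicitly
named functions.

## Numerical and design notes

- Every stage derives its seed deterministically from one master seed
  (SeedSequence spawning); identical configuration + seed reproduces every
  output file byte-for-byte, and results files contain no timestamps.
- Credible intervals are equal-tailed percentile intervals (2.5/97.5), the
  convention in trial reporting; highest-density intervals are not offered.
- Posterior summaries require ≥ 1000 draws so the tail percentiles are
  estimable.
- The calibration experiment (truth fixed at Δ, large clusters) keeps the
  outcome scale well below the 250-minute validity bound: near the bound the
  filter truncates the higher-scoring arm more, which shifts the
  noninferiority probability for reasons unrelated to posterior calibration.
- Degenerate inputs fail loudly and specifically: all-zero or all-positive
  components are redirected to single-part models, a single-school arm
  cannot be bootstrapped, an arm with no observed outcomes cannot be fit,
  and constant chains report a degenerate ESS with a warning instead of
  dividing by zero.
- Test and acceptance problem sizes: sampler oracles at 4 × 2500 draws;
  coverage and calibration at 100 synthetic trials with 4 × (500 + 1000)
  draws each; hurdle identity checks at 24 schools/arm with 4 × (400 + 600)
  draws; bootstrap oracle at 1000 vs 100 000 replicates. These sizes were
  chosen so each experiment's Monte-Carlo error is small relative to the
  property it checks.

## Known limitations

- The random-walk engine is not suited to very high-dimensional generic
  targets; the outcome models bypass it with model-specific Gibbs schemes.
- Hurdle models use observed data only; if componentwise missingness were
  informative, their estimates would inherit that bias.
- The variance-ratio summary is simulation-based and inherits Monte-Carlo
  noise proportional to 1/√n_rows per draw; its negative tail is a feature
  of the estimator, not evidence of negative clustering.
- Stratification variables influence randomisation in the generator but are
  not modelled as covariates in the analysis, matching the emulated
  analysis; no frequentist fits, model selection, or teacher-level random
  effects are provided.
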