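# Methods

## The model

Subjects move among five depressive-symptom states defined from the 10-item
CES-D short form (range 0–30; items "hopeful" and "happy" reverse-scored;
a wave is *symptomatic* when the total is ≥ 12):

1. no symptom, 2. new symptom episode, 3. symptom persistence,
4. symptom remission, 5. symptom relapse.

The permissible transitions are S = {1→2, 2→3, 2→4, 3→4, 4→5}; relapse is
absorbing within a four-wave window (re-remission after relapse is not
observable in it).  Each transition h→g has a proportional-intensity model

    λ_{i,hg}(t) = λ_{0,hg}(t) · exp(β_hg′ x_i),

on the clock-forward time scale (years since baseline), with baseline-fixed
covariates x_i.  Estimation maximizes the stacked partial likelihood over all
transitions, penalized per transition by an adaptive Lasso:

    β̂ = argmin (1/n) Σ_{hg∈S} Σ_events [ log Σ_{j∈R_h(t)} e^{β_hg′x_j} − β_hg′x_i ]
              + Σ_{hg} λ_hg Σ_r |β_hg,r| / |β̃_hg,r| ,

where R_h(t) is the delayed-entry risk set of state h just before t and β̃ is
the unpenalized maximum partial-likelihood estimate.  Coefficient vectors are
shared within *coefficient groups*; the default grouping {12}, {23},
{24, 34}, {45} treats remission out of a new episode and out of persistence
as one block (a single covariate effect on remission, stratified baselines),
matching the reporting structure of published multi-state selection tables.
Baseline hazards are always stratified by path and never estimated — the
partial likelihood conditions them out.

## State classification rules

Scores are classified sequentially: state 1 until the first symptomatic wave
(→ 2); a symptomatic wave following state 2 or 3 → 3; a non-symptomatic wave
following any symptomatic state → 4; a symptomatic wave following state 4 →
5.  At the boundary score of exactly 12 the episode rule (≥ 12 symptomatic)
takes precedence over the remission wording ("reduced to 12 or below"),
which is genuinely ambiguous in the source definitions; remission therefore
requires a score strictly below 12.  Subjects symptomatic at baseline are
excluded, as are subjects with any invalid wave (≥ 3 missing items).  With
one or two missing items the wave total imputes each missing item as the
rounded person-mean of the non-missing post-reversal items — the standard
CES-D practice; the removal rule for ≥ 3 missing items is the only one the
source states.

## Counting-process design

A subject occupying state h on the interval between waves (t_k, t_{k+1}]
contributes one record per outgoing path of h with entry t_k, exit t_{k+1},
and status 1 for the observed destination.  Contiguous censored intervals in
the same state merge, so a never-transitioning subject carries one record.
Event times sit at the wave where the new state is first observed (the right
interval endpoint); the true transition happened earlier, but interval-
censored multi-state likelihoods are out of scope and the wave-timed
approximation is the one the study design permits.  This placement makes
event times heavily tied, so the likelihood uses the Breslow tie rule
(all tied events at a time share one risk set), which keeps the objective,
gradient and Hessian closed-form and the coordinate-descent updates cheap.

## Estimation pipeline

* **Initial fit.**  Damped Newton–Raphson per coefficient group to gradient
  ∞-norm < 1e-8.  Groups with fewer events than covariates, or with a
  monotone likelihood (estimate magnitude beyond 15 on the [0,1] covariate
  scale — genuine effects never approach this), are refit with a small ridge
  (1e-3) and flagged.
* **Adaptive weights.**  w_r = 1/max(|β̃_r|, 1e-4); the 1e-4 floor caps
  weights at 1e4, effectively excluding coordinates whose initial estimate is
  numerically zero — the adaptive-Lasso intent.
* **Penalized fit.**  Cyclic coordinate descent with proximal-Newton
  soft-threshold updates and per-update backtracking (the penalized
  objective never increases), full sweeps alternating with active-set
  sweeps, convergence at max coefficient change < 1e-7; then a Newton polish
  on the active set with signs fixed.  Every fit carries a KKT certificate:
  |∂f/∂β_r| ≤ λw_r on zero coordinates and ∂f/∂β_r + λw_r·sign(β_r) = 0 on
  active ones, to 1e-5 (in practice ~1e-12 after polishing).
* **Penalty tuning.**  Per group, a 50-point descending log grid from
  λ_max (the smallest λ zeroing the group, computed from the null gradient)
  down to λ_max·1e-3, warm-started; selection by BIC = 2·n·f(β̂) +
  log(d_hg)·|active| with d_hg the group's event count (events, not
  subjects, carry the information in a partial likelihood).  The full
  criterion path is retained for audit.  Verweij–van Houwelingen
  cross-validated partial likelihood is available as an alternative
  criterion.  The source analysis does not state its tuning rule; BIC is
  this package's documented choice.
* **Inference.**  Unpenalized refit restricted to the selected active set;
  standard errors from the inverse observed information of the refit;
  two-sided normal Wald p-values; stars "**" for p ≤ 0.001 and "*" for
  0.001 < p ≤ 0.05.  The source tables show SEs only for selected
  coefficients, consistent with refit-style reporting; how they were
  actually obtained is not stated, so refit inference is a documented
  package decision (no de-biased-Lasso machinery).  Confidence limits use
  the exact 0.975 normal quantile (1.959964), and the printed effect table
  derives TRR and limits from the already-rounded (4-decimal) Est and SE so
  the printed columns are exactly self-consistent.

## Synthetic cohort generator

The generator emulates a CHARLS-like biennial aging panel: default 4,000
subjects at waves {0, 2, 4, 7} years (survey years 2011/13/15/18).  What it
reproduces, and what it does not:

* **Covariates.**  Binary covariates are Bernoulli with the published
  cohort proportions (e.g. female 46.62%, urban 21.87%); continuous ones are
  normal with the published mean/sd (age 57.88 ± 8.50, household income
  10,783.51 ± 11,056.88 yuan, chronic conditions 1.1 ± 1.17), clipped to
  plausible bounds.  Real income is heavily right-skewed and the normal
  draw clipped at zero lumps ~16% of subjects at exactly 0; real age has no
  mass below 45 while the normal tail does.  Covariate dependence (e.g.
  retirement–age) is not modeled.  Passing marginal checks therefore says
  nothing about joint structure in real data.
* **Dynamics.**  A continuous-time Markov chain over the five states with
  *constant* baseline intensities — the semiparametric baseline of the
  analysis model replaced by a constant so that closed-form exponential
  calibration checks exist.  Default true coefficients are the published
  nonzero estimates, so demo output resembles the published tables; default
  baseline intensities (0.12, 0.15, 0.50, 0.56, 0.18 per year for paths
  12/23/24/34/45) were calibrated once so the default cohort's event
  frequencies are of the published order (episodes in ≈ 36% of subjects) —
  the published event counts themselves depend on the restricted microdata
  and are not reproduction targets.
* **Observation.**  Only wave times are observed.  The observed state
  sequence is the classification rule applied to the wave-time symptomatic
  indicator (latent state ∈ {2,3,5}); latent jumps between waves are
  invisible, exactly as in the real panel.  Two consequences worth noting:
  a latent episode that remits within one interval is never observed, and a
  subject latently still in state 2 at two consecutive waves is *observed*
  as persistent.  The simulator shares the classifier's convention, so the
  emit→classify round trip is exact by construction — that property tests
  plumbing, not clinical validity.
* **Scores.**  Symptomatic waves draw a total uniformly from [12, 30],
  others from [0, 11], decomposed into 10 item responses (two stored
  pre-reversal); real CES-D totals are right-skewed near the cutoff, which
  the uniform draw does not imitate — the scores only need to be
  classification-consistent.  Optional item-level missingness masks at most
  two items per wave and only where person-mean imputation preserves the
  wave's symptomatic status, keeping classification of emitted panels exact.

## Simulation studies

The support-recovery study simulates single-transition (1→2) cohorts of
n = 3,000 with 18 candidate terms and six true effects on prevalent binary
covariates (residence −0.40, sex +0.45, education −0.45, retired −0.50,
pain +0.40, social engagement −0.35 — published-table magnitudes), baseline
intensity 0.08/yr (≈ 35% episode incidence over 7 years, like the published
cohort).  The study's interaction products are mean-centered before
multiplying: raw products of prevalent binaries correlate ~0.9 with their
parent mains and would leave the truth only weakly identifiable — the MLE
itself splits an effect between aliased columns.  The reporting pipeline
keeps raw (uncentered) products because the published coefficients are
parameterized that way; with them, near-collinear terms can legitimately
substitute for one another in sparse fits (visible in the demo, where
sex × age absorbs the sex main effect for onset).

Across 50 seeds the BIC-tuned fit recovers the full true support in ≥ 90%
of runs with well under 1.5 false positives on average.  The refit
estimates carry a systematic ~7% attenuation toward zero (max absolute bias
≈ 0.03–0.05): grouped wave-timed event times plus the Breslow tie rule
shrink estimates relative to the continuous-time truth.  This is a property
of the observation scheme, not the optimizer — fits on the exact latent
event times show no such attenuation and match R's `survival::coxph`
(Breslow, delayed entry) to < 1e-6.

## Numerical choices and degenerate inputs

* Ties: Breslow everywhere (wave-timed data make Efron's correction
  expensive inside coordinate descent and the difference immaterial at the
  observed tie fractions).
* Empty risk set at an event time: structural data error (cannot arise from
  the record builder; guarded anyway).
* Zero-event coefficient groups: skipped with a zero estimate rather than
  fit.
* MAD outlier rule: flags at |x − median| > 3 · 1.4826 · MAD; flag-only by
  default (the source reports detection, not treatment); winsorizing to the
  boundary is optional.  A zero MAD with non-constant data flags nothing
  and warns.  The multiplier 3 and the treatment are package decisions; the
  source states neither.
* Chained-equation imputation: single completion (m = 1; the source
  describes no multiple-imputation pooling), 10 sweeps of predictive mean
  matching via statsmodels, seeded; columns missing above 30% raise an
  exclusion error, mirroring the study's covariate-exclusion rule.
* Interaction screening: the cited adaptive model-free screening method is
  not re-derivable from its one-line mention; the package's documented
  stand-in ranks candidate products by the largest univariate
  partial-likelihood score statistic across paths.  The five published
  candidate pairs ship as the default list.

## Known limitations

* No death/attrition and no competing risks (the study excludes subjects
  dying before wave 4, and so does the generator's scope).
* No time-varying covariates; baseline values only.
* Interval censoring is acknowledged but not modeled; all event times are
  wave-timed, with the attenuation documented above.
* Post-selection Wald inference ignores selection uncertainty; p-values are
  conditional on the selected model, as in the source tables.
* Problem sizes in tests (cohorts of 500–3,000; 50,000 for Monte-Carlo
  marginal checks; 50-seed recovery studies) were chosen to make every
  stochastic check decisive at desk scale while the full suite stays fast.
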