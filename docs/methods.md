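# Methods

This note documents the models behind each analysis stage, the synthetic
study the package validates itself against, and the numerical and design
choices a user should know about before trusting (or extending) a result.

## The data model

An *attempt* is one tool placement: tool identity, (x, y) position in the
600×600 px play area (origin top-left, y downward, real-valued pixels), and
the time in seconds since the level started.  A participant plays each
level until they solve it or a time bound (default 60 s) expires; attempts
within a (participant, level) play are strictly ordered in time and indexed
from 1.  Files may store milliseconds (`t_ms`); values are converted to
seconds on read.  The motor pre-test contributes exactly ten speeded
point-and-click trials per participant, five at each of two target
distances (150 / 250 px); each trial records reaction time and the click's
pixel error.

## Performance metrics

Per play: solved flag, number of attempts *n*, time to first attempt `t₁`,
time to solution (timestamp of the solving attempt), and the mean
inter-attempt gap `(t_n − t₁)/(n − 1)`, i.e. the mean of consecutive
differences, defined for n ≥ 2.  The gap preceding the solving attempt is
included: it is thinking time spent before the solution.  Group analyses
condition on *solved* plays by default — behavior on unsolved levels can
reflect frustration or perseverance rather than planning — with an
all-levels variant behind the `solved_only` flag.  A play with zero
attempts counts as an unsolved exposure in the solution-rate denominator
(the time bound guarantees the participant saw the level).  The motor
summary is the per-participant median of reaction time and click error
across the ten trials; medians resist outlier trials.

## Attempt-type clustering (DP Gaussian mixture)

Placements on a level are modeled as a Dirichlet-process mixture of 2D
Gaussians:

- partition prior: Chinese restaurant process with concentration α
  (default 1.0);
- component likelihood: Gaussian with a conjugate normal-inverse-Wishart
  base NIW(μ₀, κ₀, ν₀, Ψ₀).

Defaults are data-scaled rather than standardizing the coordinates:
μ₀ = the empirical mean, κ₀ = 0.1, ν₀ = 4, Ψ₀ = diag(empirical
variances)·(ν₀ − 3), so the prior covariance mean equals the data scale.
Conjugacy gives closed-form cluster marginal likelihoods and Student-t
posterior predictives, enabling a collapsed Gibbs sampler over the
partition alone.  Defaults: 500 sweeps, 250 burn-in, fixed scan order,
deterministic given the seed.

Numerical and design choices:

- **Initialization is one singleton cluster per point.**  Collapsed Gibbs
  merges readily but splits poorly; started from a single cluster it can
  fail to separate two blobs 400 px apart within hundreds of sweeps.
- **The point estimate is the retained sweep with maximal joint
  log-probability** (CRP prior + NIW marginals), not the last sweep: it is
  reproducible and directly checkable against exact enumeration of all
  partitions at n ≤ 8 (`partition_posterior_bruteforce`, Bell(8) = 4140).
- **Responsibilities** ("probability the attempt belongs to each cluster")
  are the Gibbs conditionals under the selected partition with the point
  held out, renormalized over that partition's clusters only — no phantom
  new-cluster column — so downstream switch logic sees a fixed K.  A point
  that occupies a cluster alone keeps it via the α·prior-predictive term.
- **Cluster-count caveat.**  DP-mixture posteriors do not concentrate on
  the true number of components; with the scale-invariant base above, the
  MAP partition of single-Gaussian data has K > 1 for a substantial
  fraction of realizations at any n we tested (even n = 120 occasionally
  splits).  Cluster counts should be read as a data description, not an
  estimate of a "true K"; downstream switch rates inherit some
  label-fragmentation noise, which is why the switch-rate estimator is
  validated on generator ground-truth labels separately from the
  clustering.

## Leave-one-out group classification

For participant *p* (group A) and level ℓ, the query is their *first*
attempt.  Densities over (tool, x, y) are built from first attempts only:
the own-group density from all of A except *p*, the other-group density
from all of B.  Each density factorizes as a Laplace-smoothed categorical
over the level's tools (pseudo-count 1) times a product-Gaussian KDE with
per-dimension plug-in bandwidth `h_d = sd_d · m^(−1/6)` (m training
points); a 1 px bandwidth floor handles degenerate spreads and spatial
densities are floored at 1e−12 to avoid 0/0.  The score is
`s = p_own/(p_own + p_other)` (0.5 when both vanish); per-participant
scores are level means, and the group contrast is a two-sided one-sample
t-test of the scores against 0.5 across all scored participants.  Levels
where a group has fewer than two contributors after exclusion are skipped
and reported, never silently dropped; groups with fewer than three
participants are refused outright.

**Calibration caveat.**  Replicate-mean scores center on 0.5 under
exchangeable groups (validated to ±0.03 at the study scale), but the
t-test itself is anticonservative: participant scores share KDE training
data and are positively correlated, and the own-group density uses m − 1
participants against m for the other group, adding a small negative bias
(≈ −0.006 at 12 participants/group).  At null, rejection rates near 23%
were observed at small n instead of the nominal 5%.  Strong claims from
this test should be cross-checked, e.g. by a group-label permutation test.

## Switch statistics

Attempts are labeled by the DP mixture fit per (level, participant-group)
— positions only, tool identity ignored, all attempts (not just first) —
with data pooled across the group's participants.  The grouping scheme is
configurable (`cell`, the four age×limb cells, by default; also
`age_group`, `limb_group`, or `pooled`), reflecting that group-forming
conventions legitimately differ between a per-group and a pooled reading.
A *switch* is a consecutive attempt pair within a play whose
highest-likelihood labels differ; a group's rate is total switches over
total transitions (plays with one attempt contribute none).  The group
comparison is a mixed logistic regression of the transition-level switch
indicator on group with random intercepts for participant and level,
tested by a 1-df likelihood-ratio χ²; a pooled 2×2 contingency χ² is
available as a fallback, and all-identical outcomes are reported as
separation with no test.

## Mixed-effects group comparisons

All trial-level game analyses share one specification: fixed effects for
limb group, age group and their interaction; age in years and the median
motor reaction time as covariates with separate slopes per age group, each
centered *within* its age group so the group main effects are evaluated at
group-typical covariate values; crossed random intercepts for participants
and levels.  Links: identity for times (seconds), log for attempt counts,
logit for solving (all levels, no conditioning).  Tests are
likelihood-ratio χ² from nested maximum-likelihood refits — interaction
against the main-effects model, each main effect by dropping it from the
main-effects model — and reported effects come from the main-effects
model.  Wald CIs accompany every coefficient.

Attempt counts are modeled as Gaussian on log counts by default (the group
effect is then a multiplicative ratio, exp(coefficient)); a Poisson GLMM
is available via `family="poisson"`.

Gaussian models are fit with statsmodels' MixedLM using variance
components for the two crossed factors (ML, BFGS with a Powell fallback —
gradient methods can stall when a variance component sits at zero).  For
the logistic and Poisson models the package carries its own
Laplace-approximation GLMM with crossed random intercepts: the
random-effect modes solve the penalized score equations by damped Newton
steps, and (β, log-SDs) are optimized jointly on the Laplace objective

    l(y | β, u) − ½ u'D⁻¹u − ½ log det(I + D Z'WZ),

the same objective as lme4's `glmer` (Laplace, nAGQ = 1), against which it
is cross-checked in the test suite (fixed effects, random-effect SDs and
log-likelihood agree to ~10⁻² on a shared fixture).  All optimizers use
deterministic starts, so fits are bit-for-bit reproducible.  The motor
pre-test uses ordinary linear models (limb, age group, within-group age
slopes) with nested-model F tests.

## The synthetic study

The generator emulates a 2(age)×2(limb) study — default cell sizes 25/45
children with/without limb differences and 35/40 adults — whose group
effects default to the study population's point estimates:

| parameter | default | units |
|---|---|---|
| LD first-attempt offset | +3.79 | s |
| LD inter-attempt offset | +2.80 | s |
| child first-attempt offset | +6.1 | s |
| child inter-attempt offset | +3.5 (chosen) | s |
| LD attempts ratio | ×0.839 | — |
| switch probability | 0.39 child / 0.33 adult | — |
| motor RT mean | 3.04 child / 1.91 adult | s |
| LD motor RT offset | −0.356 | s |
| motor error mean | 7.65 child / 2.92 adult | px |
| LD motor error offset | +0.79 | px |

Mechanisms, with the reasoning for each:

- **Placements**: per level, K = 3 Gaussian clusters (sd 40 px), centers
  drawn from the seed away from the border; mixture weights and
  per-cluster tool distributions are shared by all groups, so placement
  contrasts are null by default and classification must sit at chance.
- **Attempt types** follow a first-order Markov chain: stay with
  probability 1 − switch_p, else move to a different cluster by
  renormalized weights.  Only marginal switch rates are constrained by the
  emulated study; first-order memorylessness is the minimal process
  matching them.
- **Latencies** are additive-offset lognormals (base first-attempt
  μ = 1.95, σ = 0.5; gap μ = 2.10, σ = 0.5, in log-seconds), chosen so the
  no-difference adult group averages ≈ 8 s to the first attempt and ≈ 9 s
  between attempts, keeping the population mean gap above 10 s.  Additive
  offsets make group mean differences exactly the configured estimates
  while times stay positive.  A participant random intercept (sd 1 s, a
  free parameter — the emulated study reports no within/between
  decomposition) is shared across a participant's levels.
- **Solving** is geometric: each attempt solves with a per-group
  probability; the LD probability is the age-group base divided by 0.839
  so expected attempts scale by the ratio.  Bases (adult 0.28, child 0.32)
  were calibrated once by simulation so marginal solution rates match the
  emulated 85% / 77% under the 60 s bound, and then frozen.
- **Interaction of the time bound with latencies.**  Because slower groups
  fit fewer attempts into 60 s, latency offsets alone induce a real
  attempts ratio below 1 (≈ 0.90 with the LD latency offsets and equal
  solve probabilities); the empirical LD/NLD ratio of ≈ 0.82 at the
  defaults reflects both mechanisms.  Null checks on the attempts model
  therefore require a *fully* limb-null generator.
- **Motor trials**: participant means drawn per group (between-participant
  SDs 1.58/0.79 s for RT and 3.86/1.74 px for error, matched to the
  emulated CIs), plus symmetric truncated-normal trial noise so the
  10-trial median is an unbiased read of the participant mean.
- **Reproducibility**: one seed, split hierarchically by (group,
  participant, level) with numpy `SeedSequence`-style key lists — adding
  participants or levels never perturbs existing ones.  Placements are
  kept in the play area by resampling (≤ 100 draws, then clipping);
  `generate_dataset_with_labels` exposes the true attempt-type labels as
  the oracle for label-recovery and switch-rate checks.

What the generator does *not* emulate: game physics (placements are
density samples, not simulated tool outcomes), level geometry and
tool shapes, qualitative error types, participant-level placement styles
within a group, age trends in solve probability, and the adults-only
extra level.  Passing tests therefore validate the statistical machinery
under the assumed structure, not the full richness of real logs.

## Problem sizes used in the validation suite

Parameter-recovery checks run at 40 participants per cell over 3 seeds
(timing offsets), 20 seeds for the cheap motor models, and 100 replicates
for type-I calibration of the motor F-test; sampler-vs-oracle checks use
n = 5 points (3 seeds, 6000 sweeps) where the exact posterior is
enumerable; chance-level classification uses two 40-participant groups
over 5 seeds.  These sizes keep every Monte-Carlo tolerance at ≥ 3 σ
margins while the whole suite stays practical on a single CPU.

## Known limitations

- The Laplace GLMM supports at most two crossed random-intercept factors
  and no random slopes — exactly the structure used here.
- LRT statistics from Laplace approximations can carry O(10⁻²)
  approximation noise; statistics are clipped at zero.
- The archive adapter maps common column synonyms; exotic layouts must be
  renamed by hand.
- The DP mixture treats attempts as exchangeable within a (level, group);
  it ignores within-participant dependence when forming clusters (as does
  the analysis convention it implements).
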