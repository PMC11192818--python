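# cogstyle

Analysis of attempt-level logs from a virtual tool-use game — a 2D physics
puzzle in which a participant places one of three rigid "tools" into a
600×600 px scene and physics decides whether a goal object reaches its
target. The package serves researchers comparing *cognitive styles*
(thinking more vs. acting more) across participant groups, such as children
vs. adults or people born with vs. without upper-limb differences, from
nothing but the game's behavioral logs plus a short motor pre-test.

## What it computes

Given one record per tool placement (who, which level, which tool,
where, when, solved), the package provides:

- **Performance metrics** — per level: solved flag, number of attempts
  *n*, time to first attempt *t₁*, time to solution, and thinking time
  between attempts `(t_n − t₁)/(n − 1)`; per participant: solution rate
  and solved-level averages.
- **Attempt-type clustering** — a Dirichlet-process Gaussian mixture over
  the (x, y) placements of a level, with a conjugate normal-inverse-Wishart
  base, fit by collapsed Gibbs sampling.  The Gibbs conditional for point
  *i* is `P(z_i = k) ∝ n_k^(−i) · t_k^(−i)(x_i)` for existing clusters and
  `α · t₀(x_i)` for a new one, where `t_k^(−i)` is the cluster's
  posterior-predictive Student-t.  An exact brute-force enumeration of the
  partition posterior (n ≤ 8) serves as a built-in oracle.
- **Leave-one-out group classification** — for each participant and level,
  the first attempt's relative likelihood `s = p_own/(p_own + p_other)`
  under tool×position densities built from everyone else in each group
  (Laplace-smoothed tool probabilities × product-Gaussian KDE with
  bandwidth `h_d = sd_d · m^(−1/6)`); s̄ is tested against the 0.5 chance
  level across participants.
- **Switch statistics** — consecutive attempts whose highest-likelihood
  cluster labels differ count as attempt-type switches; group rates are
  compared with a mixed logistic regression (random intercepts for
  participant and level, 1-df likelihood-ratio χ²).
- **Mixed-effects group comparisons** — Gaussian mixed models for timing
  metrics, a log-link model for attempt counts, a logistic mixed model for
  solving, all with limb group, age group, their interaction, and
  age/motor-RT covariates with separate slopes per age group; ordinary
  linear models for the motor pre-test.
- **A synthetic-study generator** with the full statistical structure the
  analyses assume (Gaussian placement mixtures, Markov attempt-type
  chains, additive-offset lognormal latencies, geometric solving under a
  60 s bound, motor trials), so every stage can be validated against known
  ground truth without any data download.

## Worked example

```python
from cogstyle import (default_study_config, generate_dataset,
                      fit_timing_model, loo_classify)

cfg = default_study_config().replace(n_per_group=40)
ds = generate_dataset(cfg, seed=11)

res = fit_timing_model(ds, "time_to_first")
print(f"LD offset: {res.limb_effect:.2f} s, CI {res.limb_effect_ci()}")
# LD offset: 3.74 s, CI (3.234530073479527, 4.249608947801315)

cls = loo_classify(ds, contrast="limb_group")
print(cls.summary())
```

The generator plants a 3.79 s limb-difference offset on the first-attempt
latency; the mixed model recovers 3.74 s with a 95% CI of [3.23, 4.25]
covering the truth.  Because both limb groups draw placements from
identical distributions by default, the classification score sits at the
0.5 chance level:

```
Leave-one-out group classification (limb_group: LD vs NLD)
  participants scored: 160 (0 participant-levels skipped)
  mean relative likelihood: 0.495 (chance 0.5)
  t(159) = -2.26, p = 0.0252
```

(The nominally significant t illustrates a caveat documented in
`docs/methods.md`: leave-one-out scores share training data, so the
one-sample t-test is anticonservative under exchangeability even though the
scores themselves center on chance.)

A command-line interface mirrors the library
(`cogstyle simulate | metrics | cluster | classify | switch | infer | run`);
`cogstyle run --config run.toml` executes the whole pipeline and writes
`report.json` / `report.md`.

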