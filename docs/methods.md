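# Methods

## Task model

Each trial starts in one of two first-stage states (two distinct advisor
pairs), sampled as a uniformly permuted, exactly balanced sequence: 150
trials, 75 per state.  Choosing advisor slot *a* in state *s* transitions
deterministically to stock `transition_map(s, a)`; within each state one slot
leads to each stock, so both stocks are reachable from both states.  The
stock pays out its current latent value, rounded half-away-from-zero to an
integer in 0–9 points (a config flag emits the continuous value instead,
since nothing in the task's logic requires integer payouts).  Latent values
evolve by independent Gaussian increments (SD = 2 points per trial) and are
reflected into [0, 9] by mirroring at the violated bound (`x → 2·bound − x`),
iterated until in range; with SD = 2 a single reflection almost always
suffices.  Initial latent values are drawn uniformly on [0, 9] per stock
unless fixed in the config.  A missed trial (response-deadline failure)
records no choice, stock or reward; the walk still advances, since task time
passes regardless of responding.

Both stocks' walks are independent — nothing in the task description
requires coupling — and trial indices are 0-based everywhere, including in
`trials.csv`.

## Hybrid learner

The agent mixes two controllers over first-stage choices (there is no
second-stage choice; the second stage is revealed by a single keypress):

- *Model-free*: cached values `Q_MF(s, a)` for the four advisor cells and
  `Q2(k)` for the two stocks, updated after each completed trial with a
  single learning rate α and eligibility trace λ:

  ```
  δ1 = Q2(k) − Q_MF(s,a)        Q_MF(s,a) += α·δ1
  δ2 = r − Q2(k)                Q2(k)     += α·δ2
                                Q_MF(s,a) += α·λ·δ2
  ```

  δ1 is computed before Q2's reward update (the conventional ordering in
  this model family; the likelihood oracle in the tests pins it).

- *Model-based*: `Q_MB(s, a) = Q2(transition_map(s, a))` — a pure lookup
  through the (known) deterministic map, so advisors sharing a stock always
  share a model-based value.

Choice follows a softmax over
`β·[w·Q_MB + (1−w)·Q_MF] + π·1[a = previous response]`, with
w ∈ [0, 1] the model-based weight, β ≥ 0 the inverse temperature and π a
perseveration bonus keyed to the previously chosen slot (the repeated motor
unit), carrying across start states and broken by missed trials.  Values
initialize at the payout-range midpoint (4.5), an unbiased starting point.
All values are in task points; β therefore operates on the 0–9 point scale.
Missed trials update nothing.

## MAP fitting

Each subject is fit independently by maximizing likelihood × prior.  The
likelihood replays the learner over the observed trials, scoring each
non-missed first-stage choice; missed trials contribute nothing and break
the perseveration chain.  Default empirical priors follow the published
lineage for this task family: α, λ, w ~ Beta(1.1, 1.1); β ~ Gamma(shape
4.82, scale 0.88); π ~ Normal(0.15, 1.42²); all are one-line config
overrides.  Optimization runs L-BFGS on unconstrained scales (logit for
unit-interval parameters, log for β — a reparameterization of the search,
not a change of target density) from `n_restarts = 10` prior-sampled starts;
ties break first-found, so a seeded generator makes fits bit-reproducible.
After fitting, the session is replayed at the MAP estimate to extract each
advisor's final model-free value (its (state, slot) cell) and final
model-based value (its stock's value) — the latent regressors of the
attitude analysis.

Recovery properties at the defaults (65 agents × 150 trials, other
parameters at the prior means): with w drawn uniformly, corr(w, ŵ) ≈ 0.88.
At a fixed generating w = 0.83 the cohort-mean estimate is mildly attenuated
(≈ 0.74–0.77 across seeds): near-deterministic choice at β ≈ 4.2 on the
point scale leaves the two controllers' predictions highly overlapping, so
per-subject estimates spread widely and the upper bound at w = 1 folds the
top of that spread downward.  This attenuation is a property of per-subject
MAP in this regime, not of the optimizer (restart counts beyond 10 change
nothing) nor of the prior (a flat prior on w shifts the mean by < 0.03).

## Stay/switch analysis

Subjects missing more than 20% of trials are excluded (a rate of exactly
20% is retained).  For each non-missed trial with at least one earlier
non-missed trial, the analysis codes `stay` (same stock reached as on the
most recent usable trial), the previous trial's reward (z-scored within
subject, sample SD), same start state (+1/−1), and their product; trials
following a miss pair with the most recent usable trial rather than being
dropped.  The inferential model is a hierarchical logistic regression with
subject-level random intercept and random slopes, variances only (no
random-effect correlations), maximizing the marginal likelihood under the
Laplace approximation via lme4's `glmer` (bobyqa), called through Rscript;
the result records the approximation, any singular-fit message (a variance
component at 0 — routine when a cohort has no true slope heterogeneity),
and whichever estimation path actually ran.  If the mixed fit fails, the
documented fallback fits per-subject logistic regressions (ridge-stabilized)
and tests coefficients across subjects with one-sample t tests.  A constant
outcome (complete separation) is flagged, not raised.

The descriptive 2×2 stay-probability table median-splits each subject's own
previous-reward distribution and reports cell means with within-subject
adjusted SEs (subject means removed, Morey small-sample correction for four
cells).  The regression, not the split, is the inferential surface.

## Attitude analysis

Liking ratings (1–7) are regressed on the final model-free and model-based
values (z-scored within subject over the four advisors), the fitted w
(z-scored between subjects), and the w-by-value products, in a hierarchical
linear model with subject-level random intercept and random slopes for the
within-subject predictors (w itself is constant within subject, so a random
w slope would be confounded with the intercept and is omitted).  Ratings are
modeled as continuous despite the ordinal scale, matching standard practice
for this design; an ordinal variant is out of scope.  Estimation is REML via
statsmodels `MixedLM` with uncorrelated variance components, using the
derivative-free Powell search first because variance components frequently
sit at the zero boundary; components estimated at exactly 0 are dropped and
the model refit so the Hessian-based SEs are finite (recorded in the result
notes).  t statistics use a containment-style approximate df
(n_obs − n_subjects − n_slopes); with 260 observations the difference from
any other df convention is immaterial.

Simple effects of model-free value at a given point of the w distribution
recenter raw w (percentiles by linear interpolation, computed on the raw
[0, 1] scale) while keeping the original between-subject SD as the scale,
rebuild the interaction columns, and refit.  Centering at the cohort mean
reproduces the main effect exactly; at other centers the fixed-effect
algebra (`b(c) = b_main + b_int·(c − mean)/SD`) holds up to the small
re-estimation of variance components that the shifted random-slope columns
induce.

## Synthetic cohort generator

The generator emulates the study's structure: 65 subjects (the planned
sample), 150 trials each, optional independent per-trial misses
(default rate 0), and four liking ratings per subject.  Agent parameters
default to the empirical-prior means (α = λ = 0.5, β = 4.2416, π = 0.15)
except w, which is drawn from Beta(2.49, 0.51) — chosen to match the
reported group profile of this task framing (mean 0.83, lower/upper
quartiles ≈ 0.70 / 1.0) while keeping genuine between-subject spread
(SD ≈ 0.19).  Any parameter can instead be fixed or given another bounded
distribution; distributions whose support escapes a parameter's bounds are
rejected at construction.

Ratings are generated from the **true** final latent values (not refits), so
downstream estimation error is attributable to the fitting stage:

```
rating = clamp(round(4 + 0.5·z(Q_MB) + (0.5 + 0.5·(1−w))·z(Q_MF) + ε), 1, 7),
ε ~ N(0, 1)
```

The (1−w) moderation makes low-w (model-free) subjects' ratings track
model-free values more strongly, the direction this task family observes.
Because misses must not update values, injecting misses into an existing
session re-simulates the agent under the miss mask rather than blanking
fields.

What the generator does *not* emulate: response times, the pre-task
transition-training phase (agents are endowed with the true map), non-RL
rating influences (halo effects, avatar appearance), within-subject rating
drift, or any coupling between miss probability and task state.  Passing
tests therefore certify the pipeline's statistical machinery under the
stated generative model, not the behavior of human raters.

A note on power at these defaults: the two liking main effects are
recovered essentially always at n = 65, but the w × MF interaction's
generative magnitude on the standardized scale is −0.5·SD(w) ≈ −0.09 while
its standard error is ≈ 0.13 (the MF and MB regressors correlate ≈ 0.7 in
this near-model-based cohort, inflating interaction SEs), so its *sign*
recovers in roughly three quarters of replications rather than reliably.
Detecting that moderation dependably would need larger cohorts, stronger
generative moderation, or less correlated value regressors than this task
produces.

## Pipeline and reproducibility

`run_full_pipeline` chains generation → exclusion → per-subject MAP →
recovery scoring → stay regression → liking regression → simple effects at
the 25th/75th percentiles of ŵ, writing all intermediate CSVs and a JSON
report.  A single top-level seed derives one child seed per stage and one
per subject (numpy `SeedSequence`), so a (spec, config, priors, seed)
quadruple reproduces every number bit-for-bit.  Problem sizes used in the
shipped analyses — 65-subject cohorts, 100-subject reference cohorts for
the stay signatures, 10 optimizer restarts, 10⁴–10⁵ walk steps for
calibration — were chosen as the smallest sizes at which the quantities of
interest are stable at desk scale.

## Known limitations

- The exact parameter set of the original model's supplementary
  specification is not public; the implemented five-parameter hybrid
  (single learning rate, slot-keyed perseveration) is the canonical form
  for this deterministic-transition variant and is documented as an
  assumption.
- Per-subject MAP attenuates cohort-mean w near the boundary (above); a
  hierarchical (group-prior) fit would shrink this but is out of scope.
- The logistic GLMM depends on an R/lme4 installation; the Python fallback
  changes the estimator (per-subject fits + t tests) and is flagged in the
  result metadata.
- Ratings are modeled linearly; floor/ceiling effects of the 1–7 scale are
  only partially captured by the generator's clamping.
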