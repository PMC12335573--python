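# Methods

## Game design

A pile holds 65 cards, 21 of which are shown. AI confidence levels form the
grid `a = k/13, k = 1..12`; each level owns two piles `r = a ± var_a`, making
the level-wise mean of `r` equal `a` exactly (calibration by construction,
verified in exact rational arithmetic — no tolerance is involved).

`var_a` defaults to `3/65`. The constraints are that `65·r` must be an
integral card count and `r ≠ 1/2`; any of `{1, 2, 3, 4}/65` satisfies them.
We use the smallest offset for which some piles *straddle* one half
(`r = 33/65` at `a = 6/13`, `r = 32/65` at `a = 7/13`): only with straddling
piles do games exist in which the AI's implied guess (red iff `a > 1/2`)
opposes the optimal guess `π*(r)`, and those games are what give the
realignment intervention any purchase on decision quality and what produce
the "misled although initially optimal" regions of the stratified matching
analysis. With `2/65` the AI would point at the optimal color in every single
game, which collapses several of the phenomena this package studies.

Shown-card deals use the Wallenius noncentral hypergeometric distribution.
The pmf is computed by exact dynamic programming over the sequential draw
process (state: reds drawn × draws made; per-step red probability
`ωR/(ωR+B)`), which for ≤ 65 cards is exact to machine precision and serves
as the oracle for the sampler; the sampler simulates the sequential draw
itself, the generative story of the game dealing cards. The classical
integral representation is deliberately not used — at these sizes the DP is
both faster and bit-reproducible.

The picked card is drawn uniformly from all 65 cards, independently of which
21 were shown, and independently for every participant-round; this is the
convention under which `P(red | A=a) = a` holds exactly. Displayed
confidences are `round(100·a)` with half-up ties.

Three attention checks (piles with 0%, ~75%, 100% reds, unbiased deals) are
inserted at timeline positions 5, 14 and 23 of the 27-round sequence,
identical across groups. A 75% pile is realized as 49 of 65 red cards, the
nearest integral count. Attention rounds never enter any statistic except the
exclusion rule.

## Synthetic participants

The generator reproduces the behavioral *structure* the analysis assumes, not
any richer psychology:

| parameter | default | meaning |
|---|---|---|
| `sigma_initial` | 12 | SD (0–100 scale) of initial confidence around `100·z` |
| `w_h` | 0.08 | logit weight per point of own confidence in the final guess |
| `w_a` | 0.08 | logit weight per point of displayed AI confidence |
| `lapse` | 0.02 | probability the final guess is a uniform coin flip |
| `inattentive_rate` | 0.05 | fraction answering attention checks uniformly |

Initial confidence is `round(clip(N(100·z, sigma_initial), 0, 100))`; the
initial guess is red iff confidence > 50 (fair coin at exactly 50); the final
guess is red with probability
`(1−lapse)·logistic(w_h·(conf−50) + w_a·(a_shown−50)) + lapse/2` — monotone
on average in both coordinates. `sigma_initial = 12` spreads confidence over
all four bins at every shown fraction without washing out its dependence on
`z`; the symmetric weights encode a player who values the AI's confidence
about as much as their own. Five participants are assigned per batch.

What the generator does **not** emulate: learning or adaptation across
rounds, individual differences in AI reliance, response times, and any
dependence of trust on experienced AI accuracy. Consequences of the fixed
logistic response rule worth knowing:

* Group differences in θ₀/θ₁ arise purely from the composition of games each
  bias condition produces (which games end up with a wrong initial guess, and
  how far the confidences sit from 50), not from differential trust. The
  directional findings for the biased groups (θ₀ much higher in away/unbiased
  than toward; θ₁ slightly lower) emerge robustly from composition alone.
* The benefit of realignment is only partially reproduced. Realignment
  reliably repairs the alignment metrics (EAE drops by roughly an order of
  magnitude on toward-distribution cohorts) and raises θ₀ by ≈ +0.05 in the
  large-sample limit, but at 100 participants/group that effect is within
  sampling noise at many seeds, and the θ₁ gain does not emerge at all
  (asymptotically ≈ −0.003): under a fixed logistic rule an extreme,
  correctly-pointing AI display is always at least as persuasive as its
  shrunken realigned value, so the harm-avoidance component of realignment
  has nothing to act on. Passing or failing these directional checks on
  synthetic cohorts therefore speaks to the behavior model, not to the
  realignment algorithm, which is tested separately against its defining
  properties.

A Bayes-observer benchmark (`bayes_observer_guess`) computes the posterior
over the two candidate piles from the exact deal likelihoods and is used as
an upper-reference for achievable accuracy.

## Alignment metrics

Stated confidence is discretized as [0,25] → very_low, [26,49] → low,
[51,75] → high, [76,100] → very_high; exactly 50 goes to high/low according
to the initial guess (the printed region bounds [26,50] and [50,75] overlap
at 50, and the tie rule is what disambiguates it). `P(Y=1 | A, H)` is
estimated per (displayed AI level, h-bin) cell; MAE/EAE are the maximum and
mean positive-part monotonicity violations over comparable ordered cell
pairs, identical pairs included in the pair count `N`.

Cells require `min_count = 10` observations by default (configurable).
Singleton cells carry estimates of exactly 0 or 1, and a max-statistic over
such cells measures sampling noise rather than misalignment — with the
threshold at 10 (the same convention the stratified heatmaps use for
display), the per-group error magnitudes and their ordering become stable and
sit in the range the human cohorts of comparable size produce.

## Realignment

Uniform-mass binning per human-confidence subspace: add uniform noise on
`[0, 1e−10/(1+1e−10)]` to the discrete AI confidences (tie-breaking, applied
at fit and at deployment), place bin edges at the empirical `k/5` quantiles,
and output each bin's mean *true* red fraction (lower variance than using
binary outcomes). Deployment values outside the training range clamp to the
extreme bins; realigned values are display-rounded to integers 0–100 before
being shown to synthetic participants. Within-training-cell means equal the
cell's mean true red fraction by construction, which is asserted as a test.
On atomic confidence distributions a refitted edge can fall inside an atom's
noise cloud, so bin membership of individual on-edge records is not
deterministic; aggregate outputs are stable (refitting on realigned outputs
moves records by < 0.01 on average).

## Utility analysis

Per-participant successes/trials of `Q′` are aggregated separately for
`Q = 0` and `Q = 1` rows, and the binomial-logit mixed model uses one fixed
coefficient per (group, Q) cell — no global intercept, hence no reference
group — plus Gaussian participant intercepts. `θ_{g,q} = logistic(β_{g,q})`
is the rate of the population-median participant (random intercept 0), which
is the quantity recovered by setting `Q` in the fixed effects. Priors:
`N(0,1)` on each `β`, half-normal(1) on the intercept SD.

Inference marginalizes the random intercepts with 21-node Gauss–Hermite
quadrature (a participant's two rows share one intercept) and samples the
remaining 9–13-dimensional posterior with an affine-invariant ensemble
sampler using differential-evolution moves: 4 independent ensembles × 16
walkers × 800 steps (300 discarded), giving 32 000 retained draws.
Convergence requires split-R̂ < 1.01 for all fixed effects, computed across
the 4 independent ensembles (each ensemble's draws, step-major, form one
chain — walkers within an ensemble are not independent, so they are not
treated as chains). Evidence ratios are posterior odds of the one-sided
hypothesis, reported as "> n_draws" when no draw violates it.

Attention-check filtering follows the rule: per check, mean and SD of stated
confidence over the reference population (all groups pooled for the study
cohorts; the calibration cohort alone for calibration data); flag deviations
beyond one SD; exclude participants flagged on more than one of the three
checks.

Boschloo's exact unconditional test delegates to `scipy.stats.boschloo_exact`
(samples as table columns, nuisance search at 64 points) and is verified
against a direct enumeration oracle over the outcome grid and a nuisance-
parameter grid.

## Problem sizes and reproducibility

The standard synthetic study uses 100 participants/group, a 300-participant
calibration cohort, 20 game batches per group (60 for calibration), and the
MCMC settings above; the full pipeline runs in about a minute on one core.
All randomness flows from one master seed through `numpy.random.SeedSequence`
spawning (per stage and per cohort), so identical seeds reproduce batches,
cohorts, maps and posterior draws bit-for-bit; the acceptance script's
`--seed` controls every stochastic stage.

## Known limitations

* The realignment utility effect on synthetic cohorts is muted (see above);
  real-data mode exists precisely because those magnitudes are properties of
  human cohorts.
* MAE is a maximum statistic and noisy at ~2400 records/group; strict
  cross-group MAE orderings should be read per-seed, EAE orderings are the
  stable ones.
* The external-dataset adapter is exercised against a synthetic stand-in
  table (the deposited tables are not bundled); its column mapping is
  configuration, not code.
* `θ` is conditioned on random intercept 0 rather than marginalized over the
  intercept distribution; with logit links the two differ slightly for rates
  near the boundary.
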