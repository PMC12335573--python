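"""Does alignment pay off? Bayesian A/B tests of conditional matching rates.

For each scored game, Q marks whether the initial guess matched the optimal
guess pi*(r) and Q' whether the final guess did. The conditional matching
rates theta_0 = E[Q' | Q=0] and theta_1 = E[Q' | Q=1] are compared across
groups with a binomial-logit mixed model (one coefficient per group x Q cell,
participant random intercepts) and one-sided posterior evidence ratios.

Runs the full pipeline; takes about a minute.
"""

from cardalign.pipeline import run_study

res = run_study(seed=7, n_per_group=100, n_calibration=300)

print("posterior mean conditional matching rates:")
post3, postr = res.posterior_3group, res.posterior_realign
for g in ("toward", "away", "unbiased"):
    print(f"  {g:>10}: theta0 = {post3.theta_draws(g, 0).mean():.3f}, "
          f"theta1 = {post3.theta_draws(g, 1).mean():.3f}")
print(f"  {'realigned':>10}: theta0 = {postr.theta_draws('realigned', 0).mean():.3f}, "
      f"theta1 = {postr.theta_draws('realigned', 1).mean():.3f}")

print("\none-sided hypothesis tests:")
for name, h in res.tests.items():
    print(f"  {name:<30} diff = {h.estimate:+.3f} +- {h.est_error:.3f}, "
          f"P(hyp) = {h.post_prob:.3f}, evidence ratio {h.evidence_ratio_label}")

print()
print("A large evidence ratio for theta0 in the better-aligned groups says")
print("the AI rescued initially-wrong guesses far more often there than in")
print("the misaligned toward-bias group.")
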