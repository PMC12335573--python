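"""Dealing cards with a thumb on the scale: Wallenius biased draws.

The game shows a participant 21 of 65 cards. Under bias, every remaining red
card's odds of being dealt next are multiplied by an odds ratio omega; the
number of reds shown then follows Wallenius' noncentral hypergeometric
distribution. This script compares the exact pmf with simulation at the three
odds ratios the study design uses.
"""

import numpy as np

from cardalign import WalleniusParams, wallenius_pmf, wallenius_sample

rng = np.random.default_rng(0)
n_red = 33  # a slight red majority: 33 of 65 cards

for omega, label in [(0.25, "bias away from red"), (1.0, "no bias"),
                     (4.0, "bias toward red")]:
    params = WalleniusParams(n_draws=21, n_red=n_red, n_black=65 - n_red,
                             omega=omega)
    pmf = wallenius_pmf(params)
    mean_exact = float(np.arange(len(pmf)) @ pmf)
    draws = wallenius_sample(params, rng, size=20_000)
    print(f"omega={omega:<5} ({label:>20}): "
          f"E[reds shown] exact={mean_exact:5.2f}  simulated={draws.mean():5.2f}")

print()
print("With 33/65 reds, an unbiased deal shows ~10.7 reds of 21 on average;")
print("omega=4 pushes that above 15, omega=1/4 below 6 - the lever the study")
print("uses to steer what participants believe about the pile.")
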