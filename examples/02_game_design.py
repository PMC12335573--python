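"""A game that makes its AI calibrated by construction.

Each AI confidence level a = k/13 owns exactly two piles, r = a - 3/65 and
r = a + 3/65, so the average true red fraction at each level equals a: the
AI confidence is exactly calibrated before any participant plays. Group bias
enters only through which cards are shown, never through a or r.
"""

import numpy as np

from cardalign import DesignConfig, build_batches, design_calibration_check, enumerate_pile_types
from cardalign.design import odds_ratio

cfg = DesignConfig()
piles = enumerate_pile_types(cfg)
print(f"{len(piles)} pile types; first four:")
for p in piles[:4]:
    print(f"  a = {p.a} (shown as {round(100 * float(p.a))}), "
          f"r = {p.r} = {float(p.r):.3f}")

check = design_calibration_check(piles)
worst = max(abs(float(m - a)) for a, m in check.items())
print(f"\ncalibration by design: max |mean r - a| over levels = {worst}")

pile = piles[11]  # a = 6/13, r = 33/65: the AI leans black, the truth is red
print(f"\npile (a={pile.a}, r={pile.r}): toward-bias odds "
      f"{odds_ratio('toward', pile.r, pile.a)}, away-bias odds "
      f"{odds_ratio('away', pile.r, pile.a)}")

rng = np.random.default_rng(7)
batches = build_batches(cfg, "toward", 3, rng)
zs = [g.z_count for g in batches[0].games]
print(f"\nbatch 0 (toward bias): reds shown per game = {zs}")
print("Each batch deals one game per pile type; participants assigned to the")
print("batch all see the same deals, in their own random order.")
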