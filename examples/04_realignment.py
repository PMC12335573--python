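"""Realigning AI confidence by multicalibration.

A held-out calibration cohort plays the toward-bias game. Within each human
confidence bin, AI confidence values are split into five equal-count bins and
each bin's output is the mean true red fraction of its training games. The
fitted map turns the misaligned AI into one whose displayed confidence is
calibrated within every human-confidence subgroup.
"""

import numpy as np

from cardalign import RealignmentConfig, apply_realignment, fit_realignment
from cardalign.participants import calibration_triples
from cardalign.pipeline import simulate_study

sim = simulate_study(seed=11, n_per_group=1, n_calibration=300)
triples = calibration_triples(sim["calibration"])
rmap = fit_realignment(triples, RealignmentConfig(seed=0))

rng = np.random.default_rng(1)
print("designed AI confidence 12/13 (displayed 92), by human confidence bin:")
for h in ("very_low", "low", "high", "very_high"):
    v = apply_realignment(rmap, h, 12 / 13, rng)
    print(f"  participant feels {h:>9}: realigned AI confidence -> {v:.3f}")

print()
print("When the participant's own confidence contradicts the AI, the")
print("realigned value retreats toward what the truth actually was in such")
print("games; when they agree, it stays close to the original confidence.")
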