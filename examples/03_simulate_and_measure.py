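"""Simulate cohorts and measure human-AI misalignment.

Synthetic participants form confidence around the fraction of reds they are
shown and combine it with the displayed AI confidence when revising their
guess. Misalignment of the AI with the participants is summarized by the
maximum and expected alignment errors (MAE/EAE): monotonicity violations of
P(outcome = red | AI confidence, human confidence bin).
"""

from cardalign import alignment_summary, calibration_error
from cardalign.pipeline import simulate_study

sim = simulate_study(seed=7, n_per_group=100, n_calibration=300)

print(f"{'group':>10}  {'MAE':>6}  {'EAE':>8}  {'ECE':>6}")
for group, records in sim["records"].items():
    scored = records[records.is_attention_check == 0]
    s = alignment_summary(scored)
    ece = calibration_error(scored)
    print(f"{group:>10}  {s.mae:6.3f}  {s.eae:8.5f}  {ece:6.3f}")

print()
print("The toward-bias group shows the largest expected alignment error even")
print("though its AI is as calibrated (low ECE) as the others: calibration")
print("and alignment are different properties. Realignment repairs alignment")
print("(MAE, a maximum over cells, is noisier from one simulation to the next).")
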