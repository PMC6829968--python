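"""Strength imbalance: the ESB index tracks a programmed side-gain ratio.

When one side's amplitude gain is g times the other's (identical
coordination), the trial power is linear in the gain, so ESB should approach
(g - 1) / (g + 1).  Averages 10 seeded trials per ratio.
"""

import numpy as np

import emgsym as es
from emgsym.synthetic import TrialSpec, generate_trial

print(f"{'gain ratio g':>12} {'mean ESB':>10} {'(g-1)/(g+1)':>12}")
for g in (1.0, 1.5, 2.0, 4.0):
    esbs = [
        es.trial_indexes(
            es.preprocess_trial(generate_trial(TrialSpec(seed=s, gain_right=g, duration_s=10.0)))
        ).esb
        for s in range(10)
    ]
    print(f"{g:>12.1f} {np.mean(esbs):>+10.4f} {(g - 1) / (g + 1):>+12.4f}")

print("\nThe pipeline recovers the programmed strength asymmetry: ESB moves from")
print("0 (balanced) toward 1 as the right side dominates.")
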