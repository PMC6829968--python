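"""A healthy symmetric trial: both sides equally strong, mirrored coordination.

Generates one synthetic 20-s bimanual trial with identical gains and
coordination weights on both sides, runs the conditioning chain and the power
model, and prints the two indexes.
"""

import emgsym as es
from emgsym.synthetic import TrialSpec, generate_trial

spec = TrialSpec(seed=7)  # protocol defaults: 20 s, 1000 Hz, 0.25 Hz pacing
segment = generate_trial(spec)
envelope = es.preprocess_trial(segment)
record = es.trial_indexes(envelope)

print(f"ESB = {record.esb:+.4f}   (0 = both sides use equal electrical power)")
print(f"MCS = {record.mcs:.4f}   (1 = perfect muscle mirroring)")

powers = es.trial_powers(envelope)
coeffs = es.coordination_coefficients(powers)
print("\nright-side coordination coefficients (share of side power per muscle):")
for muscle, a_i, w_i in zip(coeffs.muscles, coeffs.a, spec.coordination_right):
    print(f"  {muscle.value:>3}: recovered {a_i:.3f}   programmed {w_i:.3f}")
print("\nRecovered shares track the generator's ground-truth weights; a value")
print("near 0.28 for the biceps says it carries ~28% of the side's power.")
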