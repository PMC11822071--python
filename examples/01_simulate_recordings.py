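"""Simulate one participant's multimodal recordings and inspect a trial.

Generates the default trial battery (24 mental-calculation + 20
visual-search trials) for two participants and prints the shape and
condition of the first few streams.
"""

import numpy as np

from cogload.synthetic import SyntheticConfig, generate_dataset

streams, participants = generate_dataset(SyntheticConfig(n_participants=2, seed=7))

print(participants.to_string(index=False))
print(f"\n{len(streams)} trial streams (44 per participant)")
for s in streams[:4]:
    print(
        f"  {s.participant_id} {s.trial_id:24s} {len(s.time):4d} samples "
        f"({len(s.time) / 150.0:.2f} s), baseline pupil {s.baseline_pupil:.2f} mm, "
        f"mean GSR {np.mean(s.gsr) / 1000.0:.0f} kOhm"
    )
# Each stream carries gaze x/y (px), pupil (mm), pulse (unitless) and skin
# resistance (Ohm) at 150 Hz; the condition label encodes task x difficulty.
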