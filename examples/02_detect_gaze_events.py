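"""Segment a gaze stream into fixations and saccades with I-DT.

Builds one synthetic trial, runs the dispersion-threshold detector and
prints the resulting event list.  Fixation durations feed the first-order
oculometrics; centroid-to-centroid distances are the saccade amplitudes.
"""

import numpy as np

from cogload.gaze import EventParams, GazeSample, detect_fixations, saccades_between
from cogload.synthetic import ParticipantProfile, default_profiles, generate_trial

stream = generate_trial(
    ParticipantProfile(participant_id="p01"),
    default_profiles()["short_easy"],
    np.random.default_rng(4),
)
samples = [
    GazeSample(time=t, x=x, y=y, pupil=p, valid=bool(v))
    for t, x, y, p, v in zip(stream.time, stream.gaze_x, stream.gaze_y, stream.pupil, stream.valid)
]
fixations = detect_fixations(samples, EventParams())  # 40 px ~ 1 deg, 100 ms minimum
saccades = saccades_between(fixations)

print(f"{len(fixations)} fixations, {len(saccades)} saccades in a 3 s answer window")
for f in fixations:
    print(f"  fixation {f.onset:5.3f}-{f.offset:5.3f} s  {f.duration_ms:6.1f} ms  "
          f"centroid ({f.centroid_x:6.1f}, {f.centroid_y:6.1f}) px")
for s in saccades:
    print(f"  saccade  amplitude {s.amplitude:6.1f} px")
# Longer fixations with shorter following saccades indicate focal attention
# (positive K); the reverse pattern indicates ambient scanning.
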