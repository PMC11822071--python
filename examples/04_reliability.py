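"""Split-half reliability of each predictor with Spearman-Brown correction.

For every feature x condition group, trials are repeatedly split into
random halves per participant; the across-participant correlation of
half-means, corrected by 2r/(1+r), estimates how stable the per-person
feature level is.
"""

from cogload.features import build_feature_table
from cogload.reliability import reliability_report
from cogload.synthetic import SyntheticConfig, generate_dataset

streams, participants = generate_dataset(SyntheticConfig(n_participants=12, seed=5))
table = build_feature_table(streams, participants)

rel = reliability_report(
    table, ["fix_dur_ms", "gsr_ohm", "hrv_s", "lhipa"], n_splits=1000, seed=0
)
print(rel.round(3).to_string(index=False))
# Coefficients near 1 mean the feature is dominated by stable individual
# differences; near 0, by trial-to-trial noise.  Features standardized per
# person (like K) have intrinsically lower split-half reliability.
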