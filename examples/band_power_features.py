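"""Extract per-region band-power features from one synthetic trial.

The trial's class amplifies theta-band amplitude in the frontal region (R2)
by 3x; the printed table shows that fingerprint surviving the full
preprocessing chain (bandpass, downsample, blink concealment, segmentation,
Welch band power).
"""

import numpy as np

from eegemo import (
    build_montage,
    build_region_features,
    derive_encoder_inputs,
    group_channels,
    preprocess_recording,
)
from eegemo.features import BAND_NAMES
from eegemo.montage import REGION_IDS
from eegemo.synthetic import SyntheticConfig, generate_trial

cfg = SyntheticConfig(seed=5)  # class 0 signature: (R2, theta, 3x)
trial = generate_trial(cfg, subject=0, class_index=0)

montage = build_montage("deap32")
groups = group_channels(trial.recording.channel_labels, montage)
segments, _ = preprocess_recording(trial.recording, blink_channel_indices=groups["R1"])
features = build_region_features(segments, montage, groups)
inputs = derive_encoder_inputs(features)

print(f"segments per channel: T = {features.n_segments}\n")
print("mean band power per region (uV^2/Hz):")
print(f"{'region':>8} " + "".join(f"{b:>10}" for b in BAND_NAMES))
for rid in REGION_IDS:
    row = features.S[rid].mean(axis=(1, 2))
    marker = "  <- theta amplified 3x" if rid == "R2" else ""
    print(f"{rid:>8} " + "".join(f"{v:10.2f}" for v in row) + marker)
# R2's theta column stands roughly an order of magnitude above the other
# regions' (amplitude x3 = power x9): that contrast is what the classifier
# learns to read.
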