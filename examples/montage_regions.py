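"""Divide a 32-electrode cap into the nine scalp regions.

Prints each region's electrodes and resolves them against a recording whose
channels arrive in scrambled order — grouping depends only on labels.
"""

import numpy as np

from eegemo import build_montage, group_channels
from eegemo.montage import REGION_NAMES

montage = build_montage("deap32")
print(f"layout {montage.layout_id}: {montage.n_channels} electrodes, 9 regions\n")
for rid, electrodes in montage.regions.items():
    print(f"  {rid} ({REGION_NAMES[rid]:>14}): {', '.join(electrodes)}")

rng = np.random.default_rng(0)
scrambled = [montage.electrodes[i] for i in rng.permutation(32)]
groups = group_channels(scrambled, montage)
print("\nchannel indices of the prefrontal group in a scrambled recording:")
print(" ", {scrambled[i]: i for i in groups["R1"]})
# Each region resolves to the right channels no matter how the file orders them.
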