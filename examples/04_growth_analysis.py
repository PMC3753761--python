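"""Quantify long-bone growth in ovo from a three-day phantom series.

The same simulated egg is "scanned" on days 13, 14 and 15; every scan is
segmented end to end, each skeleton object is measured with the
eigen-box length, and day-to-day differences of the per-class mean
lengths give growth rates in mm/day.
"""

from dataclasses import replace

import numpy as np
import pandas as pd

from ovoseg import (
    EggDetectionConfig,
    PhantomConfig,
    detect_egg,
    generate_phantom,
    growth_rates,
    object_length,
    segment_bones,
    segment_shell,
)
from ovoseg.phantom import BONE_LENGTH_TABLE

records = []
for day in (13, 14, 15):
    config = replace(PhantomConfig(), day=day, seed=300 + day).scaled(2)
    volume, truth = generate_phantom(config)
    labels = detect_egg(volume, EggDetectionConfig().scaled(2))
    labels = segment_shell(labels, volume)
    labels, objects = segment_bones(labels, volume)
    for obj in objects:
        ids = truth.bone_ids[obj.coords[:, 0], obj.coords[:, 1], obj.coords[:, 2]]
        ids = ids[ids > 0]
        if ids.size < 0.5 * obj.n_voxels:
            continue  # debris blob, not a bone
        bone = truth.bones[truth.bones.bone_id
                           == np.bincount(ids).argmax()].iloc[0]
        records.append({"specimen_id": "egg1", "bone_class": bone["class"],
                        "day": day, "length_mm": object_length(obj)})
    print(f"day {day}: {len(objects)} objects segmented")

rates = growth_rates(pd.DataFrame(records))
rates["programmed_mm_per_day"] = rates["bone_class"].map(
    lambda b: BONE_LENGTH_TABLE[b][1])
print(rates.round(3).to_string(index=False))

# Each row compares the rate recovered through the full segmentation and
# morphometry pipeline with the elongation rate the phantom was built
# with; agreement within a voxel spacing or two per day shows in ovo
# growth is measurable without ever opening the (virtual) egg.
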