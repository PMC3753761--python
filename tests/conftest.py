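"""Shared fixtures.

The expensive artifacts — the segmented half-scale phantom and the
three-day growth series — are session-scoped so the acceptance tests and
the module tests share one computation.
"""

from dataclasses import replace

import numpy as np
import pytest

from ovoseg.bones import segment_bones
from ovoseg.egg import EggDetectionConfig, detect_egg
from ovoseg.features import object_length
from ovoseg.model import SegClass
from ovoseg.phantom import PhantomConfig, generate_feature_table, generate_phantom
from ovoseg.shell import segment_shell


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))


@pytest.fixture(scope="session")
def half_scale_config() -> PhantomConfig:
    return PhantomConfig(seed=11).scaled(2)


@pytest.fixture(scope="session")
def phantom_half(half_scale_config):
    """Half-scale day-15 phantom volume and truth."""
    return generate_phantom(half_scale_config)


@pytest.fixture(scope="session")
def segmented_half(phantom_half):
    """Full segmentation of the half-scale phantom.

    Returns (volume, truth, egg_labels, final_labels, objects, history).
    """
    volume, truth = phantom_half
    egg_labels = detect_egg(volume, EggDetectionConfig().scaled(2))
    shell_labels = segment_shell(egg_labels, volume)
    history = []
    labels, objects = segment_bones(shell_labels, volume, history=history)
    return volume, truth, shell_labels, labels, objects, history


@pytest.fixture(scope="session")
def quarter_phantom():
    """Quarter-scale phantom: fast, egg-level fidelity only."""
    return generate_phantom(PhantomConfig(seed=3).scaled(4))


@pytest.fixture(scope="session")
def group1_table():
    """Annotated synthetic table with the group-1 class proportions."""
    return generate_feature_table(seed=7)


@pytest.fixture(scope="session")
def growth_series():
    """Three-day phantom series segmented end to end.

    Returns a list of (day, truth, objects) for days 13-15 of the same
    simulated egg (fixed pose, growing bones).
    """
    out = []
    for day in (13, 14, 15):
        cfg = replace(PhantomConfig(), day=day, seed=200 + day).scaled(2)
        volume, truth = generate_phantom(cfg)
        labels = detect_egg(volume, EggDetectionConfig().scaled(2))
        labels = segment_shell(labels, volume)
        labels, objects = segment_bones(labels, volume)
        out.append((day, truth, objects))
    return out


def match_objects_to_bones(truth, objects):
    """Map each segmented object to the truth bone it mostly overlaps.

    Returns {bone_id: (object, overlap_fraction)} for objects that are
    majority-bone; artifact objects are left out.
    """
    matches = {}
    for obj in objects:
        ids = truth.bone_ids[obj.coords[:, 0], obj.coords[:, 1], obj.coords[:, 2]]
        ids = ids[ids > 0]
        if ids.size < 0.5 * obj.n_voxels:
            continue
        bid = int(np.bincount(ids).argmax())
        matches[bid] = obj
    return matches


def growth_records_from_series(series):
    """Eigen-box lengths of truth-matched objects, one row per bone/day."""
    records = []
    for day, truth, objects in series:
        matches = match_objects_to_bones(truth, objects)
        for bid, obj in matches.items():
            row = truth.bones[truth.bones.bone_id == bid].iloc[0]
            records.append({
                "specimen_id": "egg1",
                "bone_class": row["class"],
                "day": day,
                "length_mm": object_length(obj),
            })
    return records
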