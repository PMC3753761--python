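"""Synthetic in ovo microCT phantoms and annotated feature tables.

The volume phantom emulates the reference acquisition: an axially aligned
ellipsoidal egg (round axial cross-sections) resting on a carbon-fiber
animal bed that runs the full length of the scan, a calcified shell, an
interior whose HU is close to the bed's (the property that forces the
morphological egg/bed split), and 14 long-bone rods — two per anatomical
class — whose mineralization increases with incubation day.  One humerus
is aimed end-on to within a couple of voxels of the shell to exercise the
shell-adjacent hard case of bone segmentation.  Gaussian partial-volume
smoothing and additive HU noise model scanner blur and detector noise.

The feature-table generator emulates annotated training data: per-class
feature distributions that are linearly non-separable (the "not of
interest" class sits inside a ring of bone classes in a latent shape
space) but separable by an RBF kernel, with separation that grows with
incubation day the way bone calcification does.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import (
    ANNOTATION_CLASSES,
    ANNOTATION_COLUMN,
    BONE_CLASSES,
    DEFAULT_SHAPE,
    DEFAULT_SPACING,
    FEATURE_COLUMNS,
    NOI,
    CTVolume,
    LabelMap,
    SegClass,
)

__all__ = [
    "BonePrimitive",
    "PhantomConfig",
    "PhantomTruth",
    "default_bones",
    "generate_phantom",
    "generate_feature_table",
    "GROUP1_CLASS_COUNTS",
    "GROUP2_CLASS_COUNTS",
]

#: Annotated-instance counts per class emulating the Group 1 training data
#: (7 bone classes then NOI; 2951 rows total).
GROUP1_CLASS_COUNTS = {
    "humerus": 51, "radius": 42, "ulna": 49, "carpometacarpus": 52,
    "femur": 51, "tibiotarsus": 53, "tarsometatarsus": 51, NOI: 2602,
}
#: Counts emulating the Group 2 test data (1203 rows total).
GROUP2_CLASS_COUNTS = {
    "humerus": 24, "radius": 16, "ulna": 22, "carpometacarpus": 24,
    "femur": 24, "tibiotarsus": 24, "tarsometatarsus": 21, NOI: 1048,
}

#: (length at d15 in mm, elongation rate in mm/day) per long-bone class.
#: Rates span the published in ovo range (~0.5-2.9 mm/day) with the crural
#: bones growing fastest.
BONE_LENGTH_TABLE = {
    "humerus": (6.5, 0.90),
    "radius": (5.5, 0.85),
    "ulna": (6.0, 0.90),
    "carpometacarpus": (3.5, 0.65),
    "femur": (8.574, 1.40),
    "tibiotarsus": (12.0, 2.55),
    "tarsometatarsus": (9.0, 2.20),
}


@dataclass
class BonePrimitive:
    """A gently curved rod standing in for one long bone."""

    name: str
    side: str  # "left" | "right"
    length_mm: float
    width_mm: float
    thickness_mm: float
    center_mm: tuple[float, float, float]  # relative to egg center
    direction: tuple[float, float, float]
    bow_mm: float = 0.3


@dataclass
class PhantomConfig:
    """Geometry, HU model and noise of the synthetic scan.

    Defaults reproduce the reference scan geometry (256 x 256 x 604 at
    isotropic 0.216032 mm).  ``scaled(2)`` yields the half-scale variant
    (128 x 128 x 302 at 0.432064 mm) used for routine desk runs.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: float = DEFAULT_SPACING
    day: int = 15
    egg_semiaxes_mm: tuple[float, float, float] = (16.0, 16.0, 24.0)
    shell_thickness_voxels: int = 4
    bed_thickness_mm: float = 3.5
    bed_width_mm: float = 26.0
    hu_air: float = -1000.0
    hu_interior: float = 40.0
    hu_bed: float = 60.0  # close to the interior on purpose
    hu_shell: float = 2200.0
    hu_bone_base: float = 700.0
    hu_bone_day_gain: float = 40.0  # mineralization increase per day past d13
    hu_artifact: float = 600.0
    bone_width_mm: float = 2.2
    bone_thickness_mm: float = 1.8
    shell_gap_voxels: int = 2  # end-on clearance of the hard-case humerus
    artifact_count: int = 2
    artifact_radius_mm: float = 1.5
    noise_sd: float = 25.0
    smoothing_sigma_voxels: float = 0.5
    include_bed: bool = True
    bones: tuple[BonePrimitive, ...] | None = None  # None -> default layout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.smoothing_sigma_voxels < 0:
            raise ValueError("noise and smoothing parameters must be >= 0")
        if not 13 <= self.day <= 19:
            raise ValueError("day of incubation must lie in [13, 19]")
        if self.shell_thickness_voxels < 1:
            raise ValueError("shell must be at least one voxel thick")

    def scaled(self, factor: int = 2) -> "PhantomConfig":
        """Same physical phantom sampled on a coarser grid."""
        shape = tuple(int(round(s / factor)) for s in self.shape)
        return replace(self, shape=shape, spacing=self.spacing * factor)

    @property
    def hu_bone(self) -> float:
        return self.hu_bone_base + self.hu_bone_day_gain * (self.day - 13)

    @property
    def egg_center_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape
        # egg sits above the scan's vertical midline so the bed fits below
        return (nx / 2 * self.spacing,
                (ny / 2 - self.bed_thickness_mm / self.spacing / 2) * self.spacing,
                nz / 2 * self.spacing)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume."""

    labels: LabelMap                  # semantic truth classes
    bone_ids: np.ndarray              # int map, 1..n_bones, 0 elsewhere
    bones: pd.DataFrame               # id, class, side, true length/volume
    artifact_mask: np.ndarray

    def bone_mask(self, bone_id: int) -> np.ndarray:
        return self.bone_ids == bone_id

    @property
    def egg_mask(self) -> np.ndarray:
        """Everything inside the outer shell surface."""
        return self.labels.mask(SegClass.SHELL, SegClass.INTERIOR,
                                SegClass.SKELETON, SegClass.TEMPORARY)


def default_bones(config: PhantomConfig) -> tuple[BonePrimitive, ...]:
    """Deterministic 14-rod layout: two rods per class on a ring.

    Wing bones sit toward the blunt half, leg bones toward the pointed
    half.  The right humerus is the shell-adjacent hard case: it points
    radially outward and stops ``shell_gap_voxels`` short of the inner
    shell surface.
    """
    a, b, c = config.egg_semiaxes_mm
    shell_mm = config.shell_thickness_voxels * config.spacing
    inner = (a - shell_mm, b - shell_mm, c - shell_mm)
    bones = []
    for k, name in enumerate(BONE_CLASSES):
        length = bone_length_for_day(name, config.day)
        for s, side in enumerate(("left", "right")):
            # one angular slot per class, sides opposite, z staggered by
            # class so neighbors stay clear of each other at every day
            phi = 2 * np.pi * k / 7.0 + (np.pi if side == "right" else 0.0)
            if name == "humerus" and side == "right":
                bones.append(_shell_case_bone(config, inner, length, phi))
                continue
            radial = 8.0
            z_off = 9.0 - 3.0 * k
            center = (radial * np.cos(phi), radial * np.sin(phi), z_off)
            tilt = 0.18
            direction = np.array([tilt * np.cos(phi), tilt * np.sin(phi), 1.0])
            direction /= np.linalg.norm(direction)
            bones.append(BonePrimitive(
                name, side, length, config.bone_width_mm,
                config.bone_thickness_mm, center, tuple(direction)))
    return tuple(bones)


def bone_length_for_day(name: str, day: int) -> float:
    base, rate = BONE_LENGTH_TABLE[name]
    return max(base + rate * (day - 15), 2.0)


def _shell_case_bone(config, inner, length, phi) -> BonePrimitive:
    """Radial rod whose far end sits just inside the shell."""
    u = np.array([np.cos(phi), np.sin(phi), 0.12])
    u /= np.linalg.norm(u)
    # distance from egg center to the inner shell surface along u
    t_max = 1.0 / np.sqrt((u[0] / inner[0]) ** 2 + (u[1] / inner[1]) ** 2
                          + (u[2] / inner[2]) ** 2)
    gap = config.shell_gap_voxels * config.spacing
    half_w = config.bone_width_mm / 2.0
    end = (t_max - gap - half_w) * u  # keep the rod's rounded tip off the shell
    center = end - (length / 2.0) * u
    return BonePrimitive("humerus", "right", length, config.bone_width_mm,
                         config.bone_thickness_mm, tuple(center), tuple(u),
                         bow_mm=0.0)


def _rod_mask(bone: BonePrimitive, grids, spacing: float) -> np.ndarray:
    """Voxel mask of a curved elliptical-section rod (cropped arrays)."""
    X, Y, Z = grids
    u = np.asarray(bone.direction, dtype=np.float64)
    u /= np.linalg.norm(u)
    # transverse frame
    helper = np.array([0.0, 0.0, 1.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    cx, cy, cz = bone.center_mm
    dx, dy, dz = X - cx, Y - cy, Z - cz
    t = dx * u[0] + dy * u[1] + dz * u[2]
    half = bone.length_mm / 2.0
    tc = np.clip(t, -half, half)
    # gentle bow perpendicular to the axis
    bow = bone.bow_mm * (1.0 - (tc / half) ** 2) if half > 0 else 0.0
    pv = dx * v[0] + dy * v[1] + dz * v[2] - bow
    pw = dx * w[0] + dy * w[1] + dz * w[2]
    axial = np.abs(t) - half
    rv = bone.width_mm / 2.0
    rw = bone.thickness_mm / 2.0
    inside_sec = (pv / rv) ** 2 + (pw / rw) ** 2 <= 1.0
    return inside_sec & (axial <= 0)


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, PhantomTruth]:
    """Render the phantom volume and its ground truth.

    Deterministic for a fixed config (the config carries the seed).
    Raises if any bone does not fit inside the egg interior.
    """
    nx, ny, nz = config.shape
    s = config.spacing
    cx, cy, cz = config.egg_center_mm
    x = (np.arange(nx) + 0.5) * s
    y = (np.arange(ny) + 0.5) * s
    z = (np.arange(nz) + 0.5) * s
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    a, b, c = config.egg_semiaxes_mm
    shell_mm = config.shell_thickness_voxels * s
    r2_outer = (((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2)
    r2_inner = (((X - cx) / (a - shell_mm)) ** 2
                + ((Y - cy) / (b - shell_mm)) ** 2
                + ((Z - cz) / (c - shell_mm)) ** 2)
    outer = r2_outer <= 1.0
    inner = r2_inner <= 1.0
    shell = outer & ~inner

    labels = np.full(config.shape, int(SegClass.BACKGROUND), dtype=np.uint8)
    hu = np.full(config.shape, config.hu_air, dtype=np.float32)

    if config.include_bed:
        bed_top = cy + b  # tangent to the egg's lowest point
        bed = ((Y >= bed_top) & (Y <= bed_top + config.bed_thickness_mm)
               & (np.abs(X - cx) <= config.bed_width_mm / 2.0)
               & ~outer)
        bed = np.broadcast_to(bed, config.shape)
        labels[bed] = int(SegClass.BED)
        hu[bed] = config.hu_bed

    labels[inner] = int(SegClass.INTERIOR)
    hu[inner] = config.hu_interior
    labels[shell] = int(SegClass.SHELL)
    hu[shell] = config.hu_shell

    bones = config.bones if config.bones is not None else default_bones(config)
    bone_ids = np.zeros(config.shape, dtype=np.int16)
    records = []
    for bid, bone in enumerate(bones, start=1):
        absolute = replace(bone, center_mm=(bone.center_mm[0] + cx,
                                            bone.center_mm[1] + cy,
                                            bone.center_mm[2] + cz))
        mask = _rod_mask(absolute, (X, Y, Z), s)
        if not mask.any():
            raise ValueError(f"bone {bone.name}/{bone.side} rendered no voxels")
        if (mask & ~inner).any():
            raise ValueError(
                f"bone {bone.name}/{bone.side} does not fit inside the egg interior")
        labels[mask] = int(SegClass.SKELETON)
        bone_ids[mask] = bid
        hu[mask] = config.hu_bone
        records.append({
            "bone_id": bid, "class": bone.name, "side": bone.side,
            "length_mm": bone.length_mm,
            "volume_mm3": float(mask.sum()) * s ** 3,
            "day": config.day,
        })

    artifact_mask = np.zeros(config.shape, dtype=bool)
    for j in range(config.artifact_count):
        # debris blobs sit beyond the bones' z range, near the egg poles
        phi = 2 * np.pi * (j + 0.5) / max(config.artifact_count, 1) + 0.45
        z_art = cz + (18.5 if j % 2 == 0 else -18.5)
        pos = np.array([cx + 2.0 * np.cos(phi), cy + 2.0 * np.sin(phi), z_art])
        d2 = (X - pos[0]) ** 2 + (Y - pos[1]) ** 2 + (Z - pos[2]) ** 2
        blob = (d2 <= config.artifact_radius_mm ** 2) & inner & (bone_ids == 0)
        artifact_mask |= blob
        labels[blob] = int(SegClass.TEMPORARY)  # truth code for non-bone debris
        hu[blob] = config.hu_artifact

    if config.smoothing_sigma_voxels > 0:
        hu = ndimage.gaussian_filter(hu, config.smoothing_sigma_voxels)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        hu = hu + rng.normal(0.0, config.noise_sd, size=hu.shape).astype(np.float32)

    volume = CTVolume(hu.astype(np.float64), (s, s, s))
    truth = PhantomTruth(
        labels=LabelMap(labels, (s, s, s)),
        bone_ids=bone_ids,
        bones=pd.DataFrame(records),
        artifact_mask=artifact_mask,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Annotated feature tables

#: Features that carry the latent class signal (everything except day,
#: the two ratio columns and the per-specimen-normalized relative volume).
_FREE_FEATURES = (
    "asymmetry", "border_length", "compactness", "elliptical_fit",
    "length", "thickness", "width",
    "radius_largest_enclosed_ellipse", "radius_smallest_enclosing_ellipse",
    "rectangular_fit", "roundness", "shape_index",
    "ct_mean", "ct_sd", "ct_skewness", "ct_min", "ct_max",
    "neighbor_count_50", "distance_nearest_skeleton", "distance_to_shell",
)

#: Plausible baseline (mean, sd) per free feature at d15; the class signal
#: is injected on top of these via a fixed latent embedding.
_FEATURE_BASELINES = {
    "asymmetry": (0.75, 0.08),
    "border_length": (160.0, 40.0),
    "compactness": (0.45, 0.08),
    "elliptical_fit": (0.55, 0.08),
    "length": (7.0, 1.2),
    "thickness": (1.4, 0.25),
    "width": (1.8, 0.3),
    "radius_largest_enclosed_ellipse": (0.8, 0.15),
    "radius_smallest_enclosing_ellipse": (3.6, 0.6),
    "rectangular_fit": (0.6, 0.08),
    "roundness": (0.25, 0.06),
    "shape_index": (2.2, 0.4),
    "ct_mean": (650.0, 90.0),
    "ct_sd": (140.0, 30.0),
    "ct_skewness": (0.3, 0.25),
    "ct_min": (260.0, 60.0),
    "ct_max": (1150.0, 140.0),
    "neighbor_count_50": (6.0, 1.8),
    "distance_nearest_skeleton": (1.6, 0.5),
    "distance_to_shell": (4.5, 1.3),
}


def _default_specimens(days) -> list[tuple[str, int]]:
    """Group-1-like specimen layout: 4 eggs per day, 3 on the last day."""
    days = list(days)
    specimens = []
    for d in days:
        n = 3 if (d == days[-1] and len(days) > 1) else 4
        for i in range(n):
            specimens.append((f"d{d}_egg{i + 1}", d))
    return specimens


def generate_feature_table(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    days=range(13, 20),
    specimens: list[tuple[str, int]] | None = None,
    separation: float = 4.0,
    day_gain: float = 0.3,
    within_sd: float = 1.0,
    day_sharpen: float = 0.09,
) -> pd.DataFrame:
    """Generate an annotated feature table with a known class structure.

    Each class occupies a Gaussian cluster in a latent 2D shape space:
    NOI at the origin, the seven bone classes on a surrounding ring of
    radius ``separation + day_gain * (day - 13)`` (in units of the
    baseline within-class spread) so that the classes are not linearly
    separable from NOI but are cleanly separable by an RBF kernel.
    Separability improves with incubation day the way calcification
    sharpens real features: the ring radius grows and the within-class
    spread contracts by ``day_sharpen`` per day.  The latent
    coordinates are embedded into the 20 non-derived feature columns via
    a fixed projection; ratio columns and per-specimen relative volumes
    are then derived so the table satisfies the exported-schema
    invariants exactly.

    ``counts`` defaults to the Group-1-like class counts (2951 rows).
    Deterministic for a fixed seed.
    """
    if within_sd <= 0:
        raise ValueError("degenerate covariance: within_sd must be > 0")
    if separation < 0 or day_gain < 0:
        raise ValueError("separation parameters must be >= 0")
    counts = dict(GROUP1_CLASS_COUNTS) if counts is None else counts
    bad = set(counts) - set(ANNOTATION_CLASSES)
    if bad:
        raise ValueError(f"unknown classes in counts: {sorted(bad)}")
    if any(n < 1 for n in counts.values()):
        raise ValueError("all class counts must be >= 1")
    if specimens is None:
        specimens = _default_specimens(days)

    rng = np.random.default_rng(seed)
    # fixed embedding shared by every table (independent of the data seed)
    emb_rng = np.random.default_rng(123_456)
    proj = emb_rng.normal(size=(2, len(_FREE_FEATURES)))
    proj /= np.linalg.norm(proj, axis=1, keepdims=True)

    bone_angle = {name: 2 * np.pi * k / len(BONE_CLASSES)
                  for k, name in enumerate(BONE_CLASSES)}

    rows = []
    per_spec_counter = {sid: 0 for sid, _ in specimens}
    per_spec_bones = {(sid, c): 0 for sid, _ in specimens for c in BONE_CLASSES}
    for cls in [c for c in ANNOTATION_CLASSES if c in counts]:
        n = counts[cls]
        spec_cycle = 0
        for _ in range(n):
            # round-robin specimen assignment; at most two per bone class
            for _try in range(len(specimens) * 3):
                sid, day = specimens[spec_cycle % len(specimens)]
                spec_cycle += 1
                if cls == NOI or per_spec_bones[(sid, cls)] < 2:
                    break
            if cls != NOI:
                per_spec_bones[(sid, cls)] += 1
            radius = separation + day_gain * (day - 13)
            spread = within_sd * max(1.0 - day_sharpen * (day - 13), 0.2)
            if cls == NOI:
                center = np.zeros(2)
            else:
                ang = bone_angle[cls]
                center = radius * np.array([np.cos(ang), np.sin(ang)])
            latent = center + rng.normal(0.0, spread, size=2)
            feats = {}
            signal = latent @ proj
            for f_i, fname in enumerate(_FREE_FEATURES):
                base, sd = _FEATURE_BASELINES[fname]
                noise = rng.normal(0.0, 0.1)
                feats[fname] = base + sd * (signal[f_i] + noise)
            per_spec_counter[sid] += 1
            rows.append({
                "specimen_id": sid,
                "object_id": per_spec_counter[sid],
                "day_of_incubation": day,
                ANNOTATION_COLUMN: cls,
                **feats,
            })

    table = pd.DataFrame(rows)
    # keep bounded features in range, then derive the dependent columns
    for col in ("compactness", "elliptical_fit", "rectangular_fit", "roundness"):
        table[col] = table[col].clip(1e-3, 1.0)
    table["asymmetry"] = table["asymmetry"].clip(0.0, 1.0)
    for col in ("length", "thickness", "width", "border_length", "ct_sd",
                "radius_largest_enclosed_ellipse",
                "radius_smallest_enclosing_ellipse",
                "distance_nearest_skeleton", "distance_to_shell"):
        table[col] = table[col].clip(lower=0.05)
    table["neighbor_count_50"] = table["neighbor_count_50"].round().clip(lower=0)
    table["length_thickness"] = table["length"] / table["thickness"]
    table["length_width"] = table["length"] / table["width"]
    raw_vol = np.exp(rng.normal(0.0, 0.6, size=len(table)))
    table["relative_volume"] = raw_vol
    table["relative_volume"] /= table.groupby("specimen_id")[
        "relative_volume"].transform("sum")
    cols = ["specimen_id", "object_id"] + list(FEATURE_COLUMNS) + [ANNOTATION_COLUMN]
    return table[cols].reset_index(drop=True)
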