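"""Egg detection: isolate the refined Egg object from air, bed and periphery.

Stage 1 of the rule set, in three steps:

1. ``separate_background`` — a large Gaussian blur followed by a cut on
   the min-max normalized layer discards air; only the largest remaining
   object (egg plus animal bed) is kept.
2. ``split_egg_from_bed`` — the carbon-fiber bed has HU close to the egg
   interior, so the split is morphological: per axial slice, sub-objects
   below a roundness threshold are peeled off; the bed is then modeled
   from the peeled material and the background by an automatic
   threshold; the round egg core is regrown under surface tension
   (first along z, then in-plane, with the bed class blocking the
   front); and finally the bed is grown along z through the coarse
   object to excise its remnants.
3. ``refine_egg`` — a fixed threshold (coarse-egg mean + 500 HU) seeds
   the final egg, which is then smoothed by three expansion/reduction
   rounds and hole-filled into a solid object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import CTVolume, LabelMap, SegClass
from .primitives import (
    GrowSpec,
    automatic_threshold,
    connected_components,
    constrained_grow,
    largest_component,
    roundness_2d,
    smooth_object,
)

__all__ = ["EggDetectionConfig", "separate_background", "split_egg_from_bed",
           "refine_egg", "detect_egg"]

log = logging.getLogger(__name__)


@dataclass
class EggDetectionConfig:
    """Tunables of the egg-detection stage.

    The blur kernel defaults to 51 x 51 x 99 voxels at the reference
    geometry (sigma = kernel/6, so the kernel spans +-3 sigma); the
    background cut is 0.1 on the min-max normalized blurred layer; the
    egg refinement offset is +500 HU over the coarse-egg mean.  The
    roundness threshold is calibrated so axial egg cross-sections score
    well above 0.65 while bed slabs score well below.  Surface tensions:
    the z regrow accepts locally flat fronts (9/26) so thin egg caps are
    recovered while fronts along thin remnants stall; the in-plane
    regrow keeps the stringent 0.5 (nothing flat grows back); the bed
    removal pass uses a low 0.1 so it sweeps even thin bed remnants out
    of the coarse object along z.
    """

    blur_kernel: tuple[int, int, int] = (51, 51, 99)
    background_cut: float = 0.1
    roundness_min: float = 0.65
    refine_offset_hu: float = 500.0
    smoothing_rounds: int = 3
    #: 2D erosion defining slice sub-objects; deep enough to break the
    #: egg/bed contact zone and to erase the bed slab as a sub-object
    slice_split_erosion: int = 5
    theta_regrow_z: float = 9.0 / 26.0
    theta_regrow_xy: float = 0.5
    theta_bed: float = 0.1
    bed_min_separation: float = 0.85
    max_grow_iterations: int = 2000

    def __post_init__(self) -> None:
        if any(k < 1 or k % 2 == 0 for k in self.blur_kernel):
            raise ValueError("blur kernel sizes must be odd and >= 1")
        if not 0.0 < self.background_cut < 1.0:
            raise ValueError("background cut must lie in (0, 1)")
        if not 0.0 < self.roundness_min < 1.0:
            raise ValueError("roundness threshold must lie in (0, 1)")

    def scaled(self, factor: int = 2) -> "EggDetectionConfig":
        """Kernel for a volume downsampled by ``factor`` (same physical blur)."""
        kernel = tuple(max(1, int(round(k / factor)) | 1) for k in self.blur_kernel)
        return EggDetectionConfig(
            blur_kernel=kernel,
            background_cut=self.background_cut,
            roundness_min=self.roundness_min,
            refine_offset_hu=self.refine_offset_hu,
            smoothing_rounds=self.smoothing_rounds,
            slice_split_erosion=self.slice_split_erosion,
            theta_regrow_z=self.theta_regrow_z,
            theta_regrow_xy=self.theta_regrow_xy,
            theta_bed=self.theta_bed,
            bed_min_separation=self.bed_min_separation,
            max_grow_iterations=self.max_grow_iterations,
        )


def separate_background(volume: CTVolume,
                        config: EggDetectionConfig | None = None) -> LabelMap:
    """Blur, normalize, cut away air, and keep the largest object."""
    config = config or EggDetectionConfig()
    sigma = tuple(k / 6.0 for k in config.blur_kernel)
    blurred = ndimage.gaussian_filter(volume.voxels.astype(np.float32), sigma)
    vmin, vmax = float(blurred.min()), float(blurred.max())
    if vmax == vmin:
        raise ValueError("no egg found: blurred layer is constant")
    normalized = (blurred - vmin) / (vmax - vmin)
    foreground = normalized > config.background_cut
    if not foreground.any():
        raise ValueError("no egg found: everything below the background cut")
    kept = largest_component(foreground)
    labels = np.full(volume.shape, int(SegClass.BACKGROUND), dtype=np.uint8)
    labels[kept] = int(SegClass.COARSE_EGG_BED_COMPLETE)
    log.info("separate_background: %d voxels kept as coarse egg/bed",
             int(kept.sum()))
    return LabelMap(labels, volume.spacing)


def _round_cores(slice_mask: np.ndarray, config: EggDetectionConfig) -> np.ndarray:
    """Round sub-objects of one axial slice of the coarse object.

    ``slice_mask`` is the intensity-tight restriction of the coarse
    object to one slice (air skirt from the blur already excluded).  A
    2D erosion breaks the egg/bed contact zone (and erases the thin bed
    slab entirely); each surviving component is scored by roundness, and
    tight voxels within the erosion distance of a round component are
    reconstructed onto it.  Voxels farther away (the bed, or objects
    whose sub-object vanished) stay out and become Temporary.  Slices
    whose erosion leaves nothing (thin caps) yield no cores and are
    recovered by the z regrow.
    """
    erosion = config.slice_split_erosion
    if erosion > 0:
        eroded = ndimage.binary_erosion(
            slice_mask, ndimage.generate_binary_structure(2, 1),
            iterations=erosion)
    else:
        eroded = slice_mask
    lab, n = connected_components(eroded, connectivity=26)
    if n == 0:
        return np.zeros_like(slice_mask)
    round_ids = [i for i in range(1, n + 1)
                 if roundness_2d(lab == i) >= config.roundness_min]
    if not round_ids:
        return np.zeros_like(slice_mask)
    dist, (ix, iy) = ndimage.distance_transform_edt(~eroded, return_indices=True)
    nearest = lab[ix, iy]
    within = dist <= erosion + 1.5
    return slice_mask & within & np.isin(nearest, round_ids)


def _air_matter_cut(values: np.ndarray, max_depth: int = 4) -> float | None:
    """Threshold separating cold air from everything else.

    The coarse object's HU histogram is trimodal (air skirt, soft
    matter, calcified shell), and a single automatic threshold may
    isolate the bright shell minority instead.  When a cut leaves only a
    small bright fraction above it, the split is repeated on the lower
    part until the cut divides the mass into two substantial subsets —
    the air/matter boundary.
    """
    cut = automatic_threshold(values, min_separation=0.55)
    for _ in range(max_depth):
        if cut is None:
            return None
        if float(np.mean(values > cut)) >= 0.35:
            return cut
        values = values[values <= cut]
        cut = automatic_threshold(values, min_separation=0.55)
    return cut


def _tight_cut(values: np.ndarray) -> float | None:
    """Sub-object cut: the air/matter boundary pushed toward matter.

    The automatic threshold falls mid-way between the air and soft-tissue
    modes, where mostly-air partial-volume voxels still pass and bridge
    the egg/bed tangent contact.  Moving the cut toward the soft-tissue
    mode drops those voxels so the slice erosion can break the contact.
    """
    cut = _air_matter_cut(values)
    if cut is None:
        return None
    above = values[values > cut]
    if above.size == 0:
        return cut
    return cut + 0.45 * (float(np.median(above)) - cut)


def split_egg_from_bed(labels: LabelMap, volume: CTVolume,
                       config: EggDetectionConfig | None = None) -> LabelMap:
    """Morphological egg/bed split of the coarse egg/bed object."""
    config = config or EggDetectionConfig()
    labels.validate_aligned(volume)
    arr = labels.labels.copy()
    coarse = arr == int(SegClass.COARSE_EGG_BED_COMPLETE)
    if not coarse.any():
        raise ValueError("coarse egg/bed object absent")

    # The blurred coarse object carries a wide air skirt, so sub-objects
    # are defined on its intensity-tight restriction: an automatic
    # threshold inside the coarse object separates air from matter.
    matter_cut = _tight_cut(volume.voxels[coarse])
    if matter_cut is None:
        raise ValueError("no round object: coarse object has no air/matter contrast")
    tight = coarse & (volume.voxels > matter_cut)

    # slice-wise roundness test: round cores stay, the rest turns Temporary
    cores = np.zeros_like(coarse)
    for z in range(arr.shape[2]):
        sl = tight[:, :, z]
        if sl.any():
            cores[:, :, z] = _round_cores(sl, config)
    if not cores.any():
        raise ValueError("no round object: no axial slice passes the "
                         f"roundness threshold {config.roundness_min}")
    arr[coarse] = int(SegClass.TEMPORARY)
    arr[cores] = int(SegClass.COARSE_EGG_BED_PARTS)

    # model the bed before regrowing: the peeled-off bed plus the air
    # background form two separable HU subsets.  Labeling the bed first
    # blocks the regrow from leaking back into it along z.
    non_egg = (arr == int(SegClass.TEMPORARY)) | (arr == int(SegClass.BACKGROUND))
    threshold = automatic_threshold(volume.voxels[non_egg],
                                    min_separation=config.bed_min_separation)
    if threshold is not None:
        bed = non_egg & (volume.voxels > threshold)
        bed = largest_component(bed)
        arr[bed] = int(SegClass.BED)
        log.info("split_egg_from_bed: bed modeled at threshold %.1f HU "
                 "(%d voxels)", threshold, int(bed.sum()))
    else:
        log.info("split_egg_from_bed: no bed/air contrast; assuming no bed")

    # regrow the round cores: first along z, then in-plane
    work = LabelMap(arr, labels.spacing)
    work = constrained_grow(work, GrowSpec(
        SegClass.COARSE_EGG_BED_PARTS, SegClass.TEMPORARY,
        directions=("+z", "-z"), theta_st=config.theta_regrow_z,
        max_iterations=config.max_grow_iterations))
    work = constrained_grow(work, GrowSpec(
        SegClass.COARSE_EGG_BED_PARTS, SegClass.TEMPORARY,
        directions=("+x", "-x", "+y", "-y"), theta_st=config.theta_regrow_xy,
        max_iterations=config.max_grow_iterations))
    arr = work.labels
    arr[arr == int(SegClass.TEMPORARY)] = int(SegClass.BACKGROUND)

    # push the bed along z through the object to excise residual bed
    if (arr == int(SegClass.BED)).any():
        work = LabelMap(arr, labels.spacing)
        work = constrained_grow(work, GrowSpec(
            SegClass.BED, SegClass.COARSE_EGG_BED_PARTS,
            directions=("+z", "-z"), theta_st=config.theta_bed,
            max_iterations=config.max_grow_iterations))
        arr = work.labels

    arr[arr == int(SegClass.COARSE_EGG_BED_PARTS)] = int(SegClass.COARSE_EGG)
    if not (arr == int(SegClass.COARSE_EGG)).any():
        raise ValueError("no round object: egg removed during bed separation")
    return LabelMap(arr, labels.spacing)


def refine_egg(labels: LabelMap, volume: CTVolume,
               config: EggDetectionConfig | None = None) -> LabelMap:
    """Fixed-threshold refinement of the coarse egg into the final Egg."""
    config = config or EggDetectionConfig()
    labels.validate_aligned(volume)
    arr = labels.labels.copy()
    coarse = arr == int(SegClass.COARSE_EGG)
    if not coarse.any():
        raise ValueError("coarse egg object absent")
    mean_hu = float(volume.voxels[coarse].mean())
    threshold = mean_hu + config.refine_offset_hu
    seed = coarse & (volume.voxels > threshold)
    if not seed.any():
        raise ValueError(
            f"egg refinement failed: no voxel above {threshold:.1f} HU")
    egg = smooth_object(seed, config.smoothing_rounds)
    egg = ndimage.binary_fill_holes(egg)
    arr[coarse] = int(SegClass.BACKGROUND)
    egg &= arr != int(SegClass.BED)  # smoothing never claims bed voxels
    arr[egg] = int(SegClass.EGG)
    log.info("refine_egg: threshold %.1f HU, %d egg voxels",
             threshold, int(egg.sum()))
    return LabelMap(arr, labels.spacing)


def detect_egg(volume: CTVolume,
               config: EggDetectionConfig | None = None) -> LabelMap:
    """Full egg detection: background split, bed removal, refinement."""
    config = config or EggDetectionConfig()
    stages = (
        ("separate_background", lambda lm: separate_background(volume, config)),
        ("split_egg_from_bed", lambda lm: split_egg_from_bed(lm, volume, config)),
        ("refine_egg", lambda lm: refine_egg(lm, volume, config)),
    )
    labels: LabelMap | None = None
    for name, stage in stages:
        try:
            labels = stage(labels)
        except ValueError as err:
            raise ValueError(f"egg detection failed in {name}: {err}") from err
    return labels
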