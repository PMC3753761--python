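"""Bone segmentation: extract Skeleton objects from the egg interior.

Calcified bone forms a HU subset distinct from the interior, so automatic
thresholding does most of the work — except for bones lying close to the
shell, where a single threshold merges bone with shell-adjacent bright
voxels.  The stage therefore runs three nested loops:

* the **outer loop** repeats whole rounds of segmentation until a round
  adds less than a configurable fraction (default 0.005%) of new
  Skeleton voxels;
* the **first inner loop** thresholds the Interior into *Temporary
  Skeleton* / *Temporary No Skeleton 1* candidates and promotes candidate
  objects whose relative border to the *Shell Border* is at most 0.1 (on
  later outer passes they must additionally touch existing Skeleton);
* the **second inner loop** re-thresholds the unpromoted candidates,
  splitting off *Temporary No Skeleton 2* fringes, and classifies the
  remaining cores through a fuzzy set over the relative borders to the
  Shell Border and to the split-off fringe; it exits when no better
  separating threshold exists.

Rejected material is recycled into the Interior between outer passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import CTVolume, ImageObject, LabelMap, SegClass
from .primitives import automatic_threshold, connected_components, relative_border

__all__ = ["BoneSegConfig", "fuzzy_skeleton_score", "segment_bones"]

log = logging.getLogger(__name__)


@dataclass
class BoneSegConfig:
    """Tunables of the nested-loop bone segmentation."""

    #: outer loop stops when a round grows Skeleton by less than this fraction
    gain_min: float = 5e-5
    #: relative-border-to-Shell-Border cap for direct promotion
    shell_border_max: float = 0.1
    #: fuzzy membership shape over relative borders: "linear" or "sigmoid"
    membership: str = "linear"
    #: relative border at which a membership reaches zero
    membership_span: float = 0.2
    #: acceptance level on the fuzzy score
    fuzzy_cut: float = 0.5
    #: components smaller than this many voxels are discarded as noise
    min_object_voxels: int = 4
    max_outer_iterations: int = 20
    max_inner_iterations: int = 10
    #: AT homogeneity floor (see primitives.automatic_threshold)
    min_separation: float = 0.70

    def __post_init__(self) -> None:
        if self.gain_min <= 0:
            raise ValueError("gain_min must be > 0")
        if not 0.0 <= self.shell_border_max <= 1.0:
            raise ValueError("shell_border_max must lie in [0, 1]")
        if self.membership not in ("linear", "sigmoid"):
            raise ValueError("membership must be 'linear' or 'sigmoid'")


def _membership(rb: float, config: BoneSegConfig) -> float:
    """Decreasing membership of a relative border: 1 at 0, 0 at the span."""
    span = config.membership_span
    if config.membership == "linear":
        return float(np.clip(1.0 - rb / span, 0.0, 1.0))
    # logistic centered at span/2, ~1 at 0 and ~0 at span
    k = 10.0 / span
    raw = 1.0 / (1.0 + np.exp(k * (rb - span / 2.0)))
    lo = 1.0 / (1.0 + np.exp(k * span / 2.0))
    hi = 1.0 / (1.0 + np.exp(-k * span / 2.0))
    return float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))


def fuzzy_skeleton_score(rb_shell_border: float, rb_no_skeleton2: float,
                         config: BoneSegConfig | None = None) -> float:
    """Fuzzy-AND of the two border memberships of a candidate object.

    Both measurements count against the candidate: contact with the
    Shell Border suggests shell material, contact with the split-off
    *Temporary No Skeleton 2* fringe suggests the candidate is itself
    fringe.  The memberships are combined by minimum (fuzzy AND); a
    score of at least ``fuzzy_cut`` (default 0.5) accepts the object as
    Skeleton.
    """
    config = config or BoneSegConfig()
    return min(_membership(rb_shell_border, config),
               _membership(rb_no_skeleton2, config))


def _bbox_slices(mask: np.ndarray, margin: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def segment_bones(
    labels: LabelMap,
    volume: CTVolume,
    config: BoneSegConfig | None = None,
    history: list | None = None,
) -> tuple[LabelMap, list[ImageObject]]:
    """Run the three nested loops and return Skeleton objects.

    Requires Interior and Shell Border classes (from shell segmentation).
    Skeleton voxel count is monotone non-decreasing across outer
    iterations; per-iteration gains are logged, and appended to
    ``history`` as ``(outer_pass, gained_voxels, skeleton_total)`` when a
    list is passed, so the termination criterion is auditable.
    """
    config = config or BoneSegConfig()
    labels.validate_aligned(volume)
    arr = labels.labels.copy()
    hu = volume.voxels
    if not (arr == int(SegClass.INTERIOR)).any():
        raise ValueError("Interior class absent; run shell segmentation first")

    shell_border = arr == int(SegClass.SHELL_BORDER)
    skeleton = np.zeros(arr.shape, dtype=bool)

    for outer in range(1, config.max_outer_iterations + 1):
        before = int(skeleton.sum())
        prev_threshold: float | None = None

        for _inner1 in range(config.max_inner_iterations):
            interior = arr == int(SegClass.INTERIOR)
            if not interior.any():
                break
            threshold = automatic_threshold(
                hu[interior], min_separation=config.min_separation)
            if threshold is None:
                break
            if prev_threshold is not None and np.isclose(threshold, prev_threshold,
                                                         rtol=0, atol=1e-6):
                break  # no better separating threshold
            prev_threshold = threshold

            temp_skel = interior & (hu > threshold)
            # Temporary No Skeleton 1 = interior below the cut (stays Interior)
            if not temp_skel.any():
                break
            promoted, survivors = _promote_candidates(
                temp_skel, shell_border, skeleton, outer, config)
            skeleton |= promoted
            arr[promoted] = int(SegClass.SKELETON)

            accepted2, rejected2 = _second_inner_loop(
                survivors, shell_border, hu, config)
            skeleton |= accepted2
            arr[accepted2] = int(SegClass.SKELETON)
            # rejected material returns to the Interior for the next pass
            arr[rejected2] = int(SegClass.INTERIOR)

        gained = int(skeleton.sum()) - before
        denom = max(int(skeleton.sum()), 1)
        log.info("segment_bones: outer pass %d gained %d voxels (%.5f%%)",
                 outer, gained, 100.0 * gained / denom)
        if history is not None:
            history.append((outer, gained, int(skeleton.sum())))
        if gained < config.gain_min * denom:
            break
    else:
        raise RuntimeError(
            f"bone segmentation did not converge within "
            f"{config.max_outer_iterations} outer iterations "
            f"(skeleton size {int(skeleton.sum())})")

    # extract from the full Skeleton class so re-running on a map that
    # already carries Skeleton objects reproduces them (idempotence)
    objects = _extract_objects(arr, arr == int(SegClass.SKELETON),
                               labels.spacing, config)
    return LabelMap(arr, labels.spacing), objects


def _promote_candidates(temp_skel, shell_border, skeleton, outer, config):
    """First-inner-loop classification of Temporary Skeleton components."""
    promoted = np.zeros_like(temp_skel)
    survivors = np.zeros_like(temp_skel)
    lab, n = connected_components(temp_skel)
    if n == 0:
        return promoted, survivors
    sl_all = _bbox_slices(temp_skel)
    for i in range(1, n + 1):
        comp_full = lab == i
        sl = _bbox_slices(comp_full)
        comp = comp_full[sl]
        rb_sb = relative_border(comp, shell_border[sl])
        ok = rb_sb <= config.shell_border_max
        if ok and outer > 1:
            ok = relative_border(comp, skeleton[sl]) > 0.0
        if ok:
            promoted |= comp_full
        else:
            survivors |= comp_full
    del sl_all
    return promoted, survivors


def _second_inner_loop(survivors, shell_border, hu, config):
    """Refine unpromoted candidates by re-thresholding plus fuzzy borders.

    Returns ``(accepted, rejected)`` masks; rejected covers both the
    split-off No-Skeleton-2 fringe and never-accepted candidate cores.
    """
    accepted = np.zeros_like(survivors)
    no_skel2 = np.zeros_like(survivors)
    current = survivors.copy()
    for _ in range(config.max_inner_iterations):
        if not current.any():
            break
        threshold = automatic_threshold(
            hu[current], min_separation=config.min_separation)
        if threshold is None:
            break  # best separating value reached
        fringe = current & (hu <= threshold)
        core = current & (hu > threshold)
        no_skel2 |= fringe
        if not core.any():
            break
        next_current = np.zeros_like(current)
        lab, n = connected_components(core)
        for i in range(1, n + 1):
            comp_full = lab == i
            sl = _bbox_slices(comp_full)
            comp = comp_full[sl]
            rb_sb = relative_border(comp, shell_border[sl])
            rb_ns2 = relative_border(comp, no_skel2[sl])
            if fuzzy_skeleton_score(rb_sb, rb_ns2, config) >= config.fuzzy_cut:
                accepted |= comp_full
            else:
                next_current |= comp_full
        current = next_current
    rejected = (no_skel2 | current) & ~accepted
    return accepted, rejected


def _extract_objects(arr, skeleton, spacing, config):
    """Connected Skeleton components as ImageObjects; tiny specks dropped."""
    objects: list[ImageObject] = []
    lab, n = connected_components(skeleton)
    next_id = 1
    for i in range(1, n + 1):
        comp = lab == i
        size = int(comp.sum())
        if size < config.min_object_voxels:
            arr[comp] = int(SegClass.INTERIOR)
            continue
        coords = np.argwhere(comp)
        objects.append(ImageObject(next_id, SegClass.SKELETON, coords, spacing))
        next_id += 1
    return objects
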