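"""Shared segmentation operators.

These are the building blocks the rule-set stages compose: automatic
thresholding with a "no further cut" exit, 2D roundness, relative border
between objects, surface-tension-constrained region growing, and
morphological smoothing.

Conventions: 26-neighborhoods for connected-component labeling,
6-neighborhoods (voxel faces) for borders and growth fronts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely import MultiPoint, minimum_bounding_radius

from .model import LabelMap, SegClass

__all__ = [
    "automatic_threshold",
    "roundness_2d",
    "relative_border",
    "GrowSpec",
    "constrained_grow",
    "smooth_object",
    "connected_components",
    "largest_component",
]

#: face-adjacency (6-neighborhood) structuring element
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
#: full 26-neighborhood structuring element
STRUCT_26 = ndimage.generate_binary_structure(3, 3)

#: unit steps for the six face directions, keyed by name
FACE_DIRECTIONS = {
    "+x": (1, 0, 0), "-x": (-1, 0, 0),
    "+y": (0, 1, 0), "-y": (0, -1, 0),
    "+z": (0, 0, 1), "-z": (0, 0, -1),
}


def automatic_threshold(
    values: np.ndarray,
    bins: int = 256,
    min_gain: float = 1e-4,
    min_separation: float = 0.70,
) -> float | None:
    """Data-driven intensity cut between two pixel subsets, or ``None``.

    Maximizes the between-class variance over a ``bins``-bin histogram
    (Otsu's criterion).  Returns ``None`` — "no better separating value"
    — when any of these hold:

    * fewer than two distinct values,
    * the best cut's between-class variance is below ``min_gain`` of the
      total variance,
    * the normalized between-class variance (Otsu's eta in [0, 1]) of the
      best cut is at most ``min_separation``.

    The separation floor plays the role of a homogeneity test: splitting
    a single Gaussian mode yields eta ~= 2/pi ~= 0.64 no matter where the
    cut falls, whereas any genuinely bimodal CT contrast in this problem
    (air/bed, shell/interior, interior/bone) scores well above 0.7.  Ties
    between equally good cuts resolve to the midpoint of the maximal
    plateau, which centers the threshold inside an empty histogram gap.

    The returned threshold ``t`` partitions values into ``<= t`` and
    ``> t`` and lies strictly between the input minimum and maximum.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        return None
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return None

    hist, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    hist = hist.astype(np.float64)
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    m0 = np.cumsum(hist * centers)[:-1]
    mean_total = (hist * centers).sum() / total
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = ((hist * centers).sum() - m0) / w1
        sigma_b = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf

    sigma_total = ((hist * (centers - mean_total) ** 2).sum()) / total
    if sigma_total <= 0:
        return None
    peak = float(sigma_b.max())
    if peak < min_gain * sigma_total:
        return None
    if peak / sigma_total <= min_separation:
        return None
    # empty-histogram gaps between modes make the criterion flat across the
    # gap; center the cut on the maximal plateau for a stable threshold
    plateau = np.flatnonzero(sigma_b >= peak * (1.0 - 1e-12))
    best = int(plateau[(len(plateau) - 1) // 2])
    return float(edges[best + 1])


def roundness_2d(mask: np.ndarray) -> float:
    """Roundness of a 2D region: enclosed radius over enclosing radius.

    ``r_in`` is the radius of the largest enclosed disc (maximum of the
    Euclidean distance transform); ``r_out`` is the radius of the minimum
    enclosing circle of the pixel centers.  A perfect disc scores ~1, an
    elongated slab close to 0.  A single pixel scores 1 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("roundness_2d expects a 2D mask")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    if n == 1:
        return 1.0
    # pad so the distance transform sees the true boundary
    padded = np.pad(mask, 1)
    r_in = float(ndimage.distance_transform_edt(padded).max())
    pts = np.argwhere(mask)
    r_out = float(minimum_bounding_radius(MultiPoint(pts.astype(float))))
    if r_out == 0.0:
        return 1.0
    return min(r_in / r_out, 1.0)


def _shift(mask: np.ndarray, step: tuple[int, int, int],
           fill: bool = False) -> np.ndarray:
    """Shift a boolean array by ``-step`` so result[i] = mask[i + step]."""
    out = np.full_like(mask, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(step):
        if s > 0:
            src[ax] = slice(s, None)
            dst[ax] = slice(None, -s)
        elif s < 0:
            src[ax] = slice(None, s)
            dst[ax] = slice(-s, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def relative_border(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Fraction of ``a``'s exposed boundary faces shared with ``b``.

    Exposed faces are faces of ``a`` voxels whose neighbor lies outside
    ``a`` (faces on the array boundary count as exposed to non-``b``).
    Returns 0 when ``a`` has no exposed faces adjacent to ``b``.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool) & ~mask_a
    if not mask_a.any():
        raise ValueError("empty object")
    to_b = 0
    exposed = 0
    for step in FACE_DIRECTIONS.values():
        outside = _shift(~mask_a, step, fill=True)  # array edge = exposed
        in_b = _shift(mask_b, step, fill=False)
        to_b += int(np.count_nonzero(mask_a & in_b))
        exposed += int(np.count_nonzero(mask_a & outside))
    if exposed == 0:
        return 0.0
    return to_b / exposed


@dataclass
class GrowSpec:
    """Specification of a constrained grow operation.

    ``theta_st`` is the surface-tension acceptance threshold: a candidate
    voxel is absorbed only if at least that fraction of its 26 neighbors
    already belongs to the seed class.  The default 0.5 is the stringent
    setting that stops fronts from leaking through narrow attachments.
    """

    seed_class: SegClass
    target_class: SegClass
    directions: tuple[str, ...] = tuple(FACE_DIRECTIONS)
    theta_st: float = 0.5
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError("directions must be nonempty")
        unknown = set(self.directions) - set(FACE_DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown directions: {sorted(unknown)}")
        if not 0.0 < self.theta_st <= 1.0:
            raise ValueError("theta_st must lie in (0, 1]")


def constrained_grow(labels: LabelMap, spec: GrowSpec) -> LabelMap:
    """Grow the seed class into the target class under surface tension.

    Each iteration simultaneously relabels every target-class voxel that
    (a) is face-adjacent to the seed class along an allowed direction and
    (b) has at least ``theta_st`` of its 26 neighbors already in the seed
    class.  Runs to fixpoint or ``max_iterations``.  Voxels of any other
    class never change, so growth is monotone in the seed set.
    """
    arr = labels.labels
    seed = arr == int(spec.seed_class)
    if not seed.any():
        raise ValueError(f"seed class {spec.seed_class.name} absent")
    target = arr == int(spec.target_class)
    if not target.any():
        return labels.copy()

    out = arr.copy()
    seed = seed.copy()
    kernel = np.ones((3, 3, 3), dtype=np.float32)
    kernel[1, 1, 1] = 0.0
    steps = [FACE_DIRECTIONS[d] for d in spec.directions]
    shape = np.asarray(seed.shape)
    for _ in range(spec.max_iterations):
        adjacent = np.zeros_like(seed)
        for step in steps:
            adjacent |= _shift(seed, step)
        candidates = target & adjacent
        idx = np.argwhere(candidates)
        if idx.size == 0:
            break
        # the neighbor-count convolution only matters around the front
        lo = np.maximum(idx.min(axis=0) - 1, 0)
        hi = np.minimum(idx.max(axis=0) + 2, shape)
        crop = tuple(slice(a, b) for a, b in zip(lo, hi))
        neighbor_frac = ndimage.convolve(
            seed[crop].astype(np.float32), kernel, mode="constant") / 26.0
        accepted = candidates[crop] & (neighbor_frac >= spec.theta_st - 1e-9)
        if not accepted.any():
            break
        seed_crop = seed[crop]
        seed_crop |= accepted
        seed[crop] = seed_crop
        target_crop = target[crop]
        target_crop &= ~accepted
        target[crop] = target_crop
    out[seed] = int(spec.seed_class)
    return LabelMap(out, labels.spacing)


def smooth_object(mask: np.ndarray, rounds: int) -> np.ndarray:
    """Morphological smoothing: ``rounds`` expansion then reduction steps.

    Implemented as binary closing with the face-adjacency element iterated
    ``rounds`` times (dilate ``rounds`` times, then erode ``rounds``
    times).  ``rounds = 0`` is the identity.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if rounds == 0 or not mask.any():
        return mask.copy()
    padded = np.pad(mask, rounds)
    closed = ndimage.binary_closing(padded, structure=STRUCT_6, iterations=rounds)
    sl = (slice(rounds, -rounds),) * mask.ndim
    return closed[sl]


def connected_components(mask: np.ndarray,
                         connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label connected components (default 26-connectivity)."""
    structure = STRUCT_26 if connectivity == 26 else STRUCT_6
    if mask.ndim == 2:
        structure = ndimage.generate_binary_structure(2, 2 if connectivity == 26 else 1)
    return ndimage.label(mask, structure=structure)


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Boolean mask of the largest connected component of ``mask``."""
    lab, n = connected_components(mask, connectivity)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))
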