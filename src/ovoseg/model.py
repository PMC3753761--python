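"""Shared data model for in ovo microCT analysis.

The pipeline works on three kinds of objects:

``CTVolume``
    a 3D scalar field of Hounsfield Units (HU) with isotropic-by-default
    voxel spacing.  Axes are ordered ``(x, y, z)`` with ``z`` the slice
    axis, which for a properly positioned egg runs from the blunt to the
    pointed end.

``LabelMap``
    a per-voxel semantic class map aligned to a ``CTVolume``.  The class
    vocabulary mirrors the rule set's object hierarchy (coarse egg/bed
    composites, shell, shell border, interior, skeleton, temporaries).

``ImageObject``
    a connected set of voxels with an identity and a class, the unit on
    which morphometric features are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: Scan geometry of the reference acquisition protocol: 604 axial slices of
#: 256 x 256 pixels at isotropic 0.216032 mm voxels.
DEFAULT_SHAPE = (256, 256, 604)
DEFAULT_SPACING = 0.216032


class SegClass(IntEnum):
    """Semantic classes used across the segmentation rule set."""

    BACKGROUND = 0
    BED = 1
    COARSE_EGG_BED_COMPLETE = 2
    COARSE_EGG_BED_PARTS = 3
    COARSE_EGG = 4
    EGG = 5
    SHELL = 6
    SHELL_BORDER = 7
    INTERIOR = 8
    TEMP_SKELETON = 9
    TEMP_NO_SKELETON_1 = 10
    TEMP_NO_SKELETON_2 = 11
    SKELETON = 12
    TEMPORARY = 13


#: The seven long-bone classes plus "not of interest", in report order.
BONE_CLASSES = (
    "humerus",
    "radius",
    "ulna",
    "carpometacarpus",
    "femur",
    "tibiotarsus",
    "tarsometatarsus",
)
NOI = "NOI"
ANNOTATION_CLASSES = BONE_CLASSES + (NOI,)

#: Exported per-object feature columns, in CSV order.
FEATURE_COLUMNS = (
    "day_of_incubation",
    "asymmetry",
    "border_length",
    "compactness",
    "elliptical_fit",
    "length",
    "thickness",
    "width",
    "length_thickness",
    "length_width",
    "relative_volume",
    "radius_largest_enclosed_ellipse",
    "radius_smallest_enclosing_ellipse",
    "rectangular_fit",
    "roundness",
    "shape_index",
    "ct_mean",
    "ct_sd",
    "ct_skewness",
    "ct_min",
    "ct_max",
    "neighbor_count_50",
    "distance_nearest_skeleton",
    "distance_to_shell",
)
ID_COLUMNS = ("specimen_id", "object_id")
ANNOTATION_COLUMN = "annotation"


@dataclass
class CTVolume:
    """A 3D CT volume calibrated to Hounsfield Units.

    Parameters
    ----------
    voxels:
        3D float array of HU values, axis order ``(x, y, z)``.
    spacing:
        voxel edge lengths in mm per axis.
    origin:
        physical offset of voxel (0, 0, 0) in mm (voxel-centered).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING,) * 3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3D array")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1


@dataclass
class LabelMap:
    """Per-voxel semantic class map aligned to a :class:`CTVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING,) * 3

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap requires a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.uint8)
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *classes: SegClass) -> np.ndarray:
        """Boolean mask of the voxels carrying any of the given classes."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in classes:
            out |= self.labels == int(c)
        return out

    def count(self, cls: SegClass) -> int:
        return int(np.count_nonzero(self.labels == int(cls)))

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.spacing)

    def validate_aligned(self, volume: CTVolume) -> None:
        if self.labels.shape != volume.voxels.shape:
            raise ValueError(
                f"label map shape {self.labels.shape} does not match "
                f"volume shape {volume.voxels.shape}"
            )


@dataclass
class ImageObject:
    """A connected voxel set with identity and class.

    ``coords`` is an ``(n, 3)`` integer array of voxel indices.
    """

    id: int
    cls: str | SegClass
    coords: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING,) * 3
    specimen_id: str = "specimen"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        if self.coords.shape[1] != 3 or self.coords.shape[0] == 0:
            raise ValueError("coords must be a nonempty (n, 3) index array")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def volume(self) -> float:
        """Physical volume in mm^3 (voxel count x voxel volume)."""
        return self.n_voxels * float(np.prod(self.spacing))

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_index, max_index) inclusive per axis."""
        return self.coords.min(axis=0), self.coords.max(axis=0)

    @property
    def centroid_mm(self) -> np.ndarray:
        return self.coords.mean(axis=0) * np.asarray(self.spacing)

    def mask(self, shape: tuple[int, int, int] | None = None,
             margin: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Dense boolean mask of the object on a cropped grid.

        Returns ``(mask, offset)`` where ``offset`` is the index of the
        crop origin in the full volume.  If ``shape`` is given the crop is
        clipped to it.
        """
        lo, hi = self.bounding_box
        lo = np.maximum(lo - margin, 0)
        hi = hi + margin
        if shape is not None:
            hi = np.minimum(hi, np.asarray(shape) - 1)
        size = hi - lo + 1
        m = np.zeros(tuple(size), dtype=bool)
        rel = self.coords - lo
        m[rel[:, 0], rel[:, 1], rel[:, 2]] = True
        return m, lo
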