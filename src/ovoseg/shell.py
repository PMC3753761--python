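"""Shell segmentation: split the Egg into Shell, Shell Border and Interior.

The calcified shell and the egg interior form two well-separated HU
subsets, so a single automatic threshold suffices.  The shell is then
flanked on its interior side by a two-voxel *Shell Border* layer; the
downstream bone stage uses contact with that layer to recognize objects
glued to the shell.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .model import CTVolume, LabelMap, SegClass
from .primitives import STRUCT_6, automatic_threshold

__all__ = ["segment_shell"]

log = logging.getLogger(__name__)


def segment_shell(labels: LabelMap, volume: CTVolume,
                  border_layers: int = 2) -> LabelMap:
    """Threshold the Egg into Shell and Interior and carve the Shell Border.

    The border is built by ``border_layers`` face-dilation passes of the
    shell restricted to interior voxels, i.e. it sits on the interior
    side of the shell and is (up to) two voxels thick.
    """
    labels.validate_aligned(volume)
    arr = labels.labels.copy()
    egg = arr == int(SegClass.EGG)
    if not egg.any():
        raise ValueError("Egg class absent; run egg detection first")

    threshold = automatic_threshold(volume.voxels[egg])
    if threshold is None:
        raise ValueError("shell not separable: no HU contrast inside the egg")
    shell = egg & (volume.voxels > threshold)
    interior = egg & ~shell
    if not shell.any() or not interior.any():
        raise ValueError("shell not separable: threshold left one side empty")

    border = np.zeros_like(shell)
    frontier = shell
    for _ in range(border_layers):
        frontier = ndimage.binary_dilation(frontier, STRUCT_6) & interior & ~border
        border |= frontier

    arr[shell] = int(SegClass.SHELL)
    arr[interior] = int(SegClass.INTERIOR)
    arr[border] = int(SegClass.SHELL_BORDER)
    log.info("segment_shell: threshold %.1f HU, shell %d, border %d, interior %d",
             threshold, int(shell.sum()), int(border.sum()),
             int(interior.sum() - border.sum()))
    return LabelMap(arr, labels.spacing)
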