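"""From a regressed signed distance map to cell, synapse and surface masks.

The distance map is thresholded at ±54.5 nm (about a quarter of the
218.5 nm voxel pitch): voxels above +threshold form the effector, below
-threshold the target, each reduced to its largest 26-connected
component.  The immunological-synapse mask is the overlap of the two cell
masks dilated by a length comparable to the axial resolution (two voxels,
437 nm, by default).  Surface and interior partition each cell mask by a
one-voxel (218 nm) binary erosion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .io import CellMaskPair, ShapeError, ValidationError, logger
from .distnet import SignedDistanceMap

#: default distance threshold (nm) separating cell from background
DEFAULT_THRESHOLD_NM = 54.5

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CROSS6 = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """An operation that needs a nonempty mask received an empty one."""


@dataclass
class ISMask:
    """Binary immunological-synapse region."""

    values: np.ndarray
    pitch: tuple[float, float, float]
    dilation_voxels: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ShapeError("IS mask must be 3D")


def largest_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Largest 26-connected component; returns (component, removed voxels)."""
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n <= 1:
        return mask.copy(), 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    out = labels == keep
    return out, int(mask.sum() - out.sum())


def masks_from_distmap(
    y: SignedDistanceMap,
    threshold_nm: float = DEFAULT_THRESHOLD_NM,
    keep_largest: bool = True,
) -> CellMaskPair:
    """Threshold the signed distance map into effector and target masks.

    effector = {y * pitch > +threshold}, target = {y * pitch < -threshold};
    each mask is optionally reduced to its largest 26-connected component
    (toy models can fragment; the removed voxel count is logged).
    """
    if threshold_nm <= 0:
        raise ValidationError("distance threshold must be positive")
    nm = y.to_nm()
    eff = nm > threshold_nm
    tgt = nm < -threshold_nm
    if keep_largest:
        removed = 0
        if eff.any():
            eff, r = largest_component(eff)
            removed += r
        if tgt.any():
            tgt, r = largest_component(tgt)
            removed += r
        if removed:
            logger.info("masks_from_distmap: removed %d voxels in minor "
                        "components", removed)
    if not eff.any() and not tgt.any():
        logger.warning("masks_from_distmap: both masks are empty")
    return CellMaskPair(effector=eff, target=tgt, pitch=y.pitch)


def synapse_mask(pair: CellMaskPair, dilation_voxels: int = 2) -> ISMask:
    """IS = dilate(effector, ball r) intersected with dilate(target, ball r).

    The default two-voxel radius matches the axial resolution of the
    tomographic system (437 nm at 218.5 nm pitch).  With r = 0 the masks
    are disjoint, so the synapse is empty by construction.
    """
    if dilation_voxels < 0:
        raise ValidationError("dilation radius must be >= 0")
    if dilation_voxels == 0:
        values = pair.effector & pair.target  # disjoint -> empty
    else:
        selem = ball(dilation_voxels)
        de = ndimage.binary_dilation(pair.effector, structure=selem)
        dt = ndimage.binary_dilation(pair.target, structure=selem)
        values = de & dt
    return ISMask(values=values, pitch=pair.pitch, dilation_voxels=dilation_voxels)


def surface_interior(
    mask: np.ndarray,
    erosion_voxels: int = 1,
    pitch: tuple[float, float, float] = (218.5,) * 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a cell mask into its one-voxel surface shell and interior.

    interior = erosion by the 6-connected cross repeated ``erosion_voxels``
    times; surface = mask minus interior.  The two exactly partition the
    input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot split an empty mask into surface/interior")
    if erosion_voxels < 0:
        raise ValidationError("erosion radius must be >= 0")
    if erosion_voxels == 0:
        interior = mask.copy()
    else:
        interior = ndimage.binary_erosion(mask, structure=_CROSS6,
                                          iterations=erosion_voxels)
    surface = mask & ~interior
    return surface, interior
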