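"""Cylindrical analysis region centered at the bregma landmark.

The assay restricts pit volumetry to a circular region of interest centered
at bregma (the junction of the coronal and sagittal sutures); a 7 mm diameter
works well for 5-week mouse calvaria.  The ROI is realized as a cylinder
whose axis runs along z (normal to the slice plane) so that both the outer
and inner plate surfaces fall inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import BinaryMask, VoxelVolume, require_same_grid


@dataclass(frozen=True)
class ROISpec:
    """Cylinder definition: center voxel (bregma), in-plane diameter, z extent.

    ``z_extent`` is either ``None`` (full depth) or a half-open ``(z0, z1)``
    slice range.
    """

    center_voxel: tuple[int, int, int]
    diameter_mm: float = 7.0
    z_extent: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if len(self.center_voxel) != 3:
            raise ValueError("center_voxel must be a (z, y, x) triple")


def cylindrical_roi_mask(vol: VoxelVolume, spec: ROISpec) -> BinaryMask:
    """Mask of voxels whose center lies within ``diameter/2`` of the cylinder
    axis (inclusive boundary), within the requested z range."""
    nz, ny, nx = vol.shape
    cz, cy, cx = spec.center_voxel
    if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
        raise ValueError(f"ROI center {spec.center_voxel} outside volume {vol.shape}")
    radius_um = spec.diameter_mm * 1000.0 / 2.0
    vs = vol.voxel_size_um
    yy = (np.arange(ny, dtype=np.float64) - cy) * vs
    xx = (np.arange(nx, dtype=np.float64) - cx) * vs
    disc = yy[:, None] ** 2 + xx[None, :] ** 2 <= radius_um**2
    zsel = np.zeros(nz, dtype=bool)
    if spec.z_extent is None:
        zsel[:] = True
    else:
        z0, z1 = spec.z_extent
        if not (0 <= z0 < z1 <= nz):
            raise ValueError(f"invalid z_extent {spec.z_extent} for {nz} slices")
        zsel[z0:z1] = True
    mask = zsel[:, None, None] & disc[None, :, :]
    return BinaryMask(mask, vol.voxel_size_um, vol.origin_um)


def restrict_to_roi(mask: BinaryMask, roi: BinaryMask) -> BinaryMask:
    """Voxelwise AND of a mask with the ROI."""
    require_same_grid(mask, roi)
    return BinaryMask.like(mask, mask.data & roi.data)
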