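"""End-to-end analysis pipeline: segment -> ROI -> pit isolation -> label.

The stages mirror the semi-automated workflow: threshold the reconstructed
volume, keep the main bone component, intersect with the bregma-centered
cylindrical ROI, close-and-fill, subtract, and label the pit candidates.
Review and summarization live in :mod:`calvapit.review` / :mod:`calvapit.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import pits as pits_mod
from . import roi as roi_mod
from . import segment
from .volio import BinaryMask, VoxelVolume

DEFAULT_ROI_DIAMETER_MM = 7.0
#: ball/disc radius for close-and-fill; must exceed the widest expected pit
#: opening radius so that lids span every mouth.
DEFAULT_CLOSING_RADIUS_UM = 150.0
#: default minimum candidate size, in voxels, converted per-volume to μm³.
DEFAULT_MIN_PIT_VOXELS = 30


@dataclass(frozen=True)
class AnalysisResult:
    threshold_value: float
    bone: BinaryMask
    roi_mask: BinaryMask
    filled: BinaryMask
    pit_mask: BinaryMask
    candidates: list[pits_mod.PitCandidate]


def analyze_volume(
    vol: VoxelVolume,
    bregma_voxel: tuple[int, int, int],
    threshold: float | str = "otsu",
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
    closing_radius_um: float = DEFAULT_CLOSING_RADIUS_UM,
    min_pit_volume_um3: float | None = None,
    keep_largest_bone: bool = True,
    smoothing_sigma_um: float | None = None,
) -> AnalysisResult:
    """Run the full pit-isolation pipeline on one volume.

    ``threshold`` is either a numeric intensity or ``"otsu"``.
    ``min_pit_volume_um3`` defaults to 30 voxels at the volume's voxel size.
    ``smoothing_sigma_um`` defaults to half a voxel of Gaussian
    pre-smoothing — enough to keep voxel noise from roughening the
    thresholded surface, small enough not to shrink the smallest cavities;
    pass 0 to threshold the raw volume.
    """
    if smoothing_sigma_um is None:
        smoothing_sigma_um = vol.voxel_size_um / 2.0
    smoothed = segment.denoise(vol, smoothing_sigma_um)
    if threshold == "otsu":
        t = segment.threshold_otsu(smoothed)
    else:
        t = float(threshold)
    bone = segment.threshold_fixed(smoothed, t)
    if keep_largest_bone:
        bone = segment.largest_component(bone)
    roi_spec = roi_mod.ROISpec(center_voxel=tuple(bregma_voxel), diameter_mm=roi_diameter_mm)
    roi_mask = roi_mod.cylindrical_roi_mask(vol, roi_spec)
    filled = pits_mod.close_and_fill(bone, roi_mask, closing_radius_um)
    pit_mask = pits_mod.extract_pit_fill(filled, bone, roi_mask)
    if min_pit_volume_um3 is None:
        min_pit_volume_um3 = DEFAULT_MIN_PIT_VOXELS * vol.voxel_volume_um3
    candidates = pits_mod.label_candidates(
        pit_mask, bone, min_volume_um3=min_pit_volume_um3, roi=roi_mask
    )
    return AnalysisResult(t, bone, roi_mask, filled, pit_mask, candidates)
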