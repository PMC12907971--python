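"""Core resorption-pit isolation: close-and-fill, subtract, label.

The measurement principle: morphologically close the bone within the ROI
with a ball whose radius exceeds the widest pit's carving radius, fill any
enclosed cavities, and subtract the original bone.  What remains is the
"filled rendering" of every surface concavity and pore — the candidate
resorption pits — whose voxel counts convert directly to resorbed volume.

Closing is computed by thresholding exact Euclidean distance transforms,
which is identical to dilation followed by erosion with the discrete ball
footprint ``{offset : |offset| <= r}`` but costs O(n) regardless of radius.
The volume is padded with background by the ball radius first, so border
behaviour is as if empty space extended outward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .segment import connectivity_structure
from .volio import BinaryMask, require_same_grid

SURFACE_CLASSES = ("outer", "inner", "through", "internal")

#: background (fill / surface classification) connectivity is 6, the standard
#: complement of 26-connected foreground.
_BG_STRUCTURE = ndi.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PitCandidate:
    """One labeled pit-fill component.

    Ids run 1..N ordered by descending voxel count, ties broken by
    lexicographic (z, y, x) centroid.  ``bbox`` is half-open
    (z0, z1, y0, y1, x0, x1).
    """

    pit_id: int
    voxel_count: int
    volume_um3: float
    centroid_voxel: tuple[float, float, float]
    bbox: tuple[int, int, int, int, int, int]
    surface_class: str
    touches_roi_boundary: bool
    status: str = "candidate"


def _disc_footprint(r_vox: float) -> np.ndarray:
    n = int(np.floor(r_vox))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return yy**2 + xx**2 <= r_vox**2


def _lid_fill(mask: np.ndarray, r_vox: float) -> np.ndarray:
    """Fill each (y, x) column between the flat-disc-lidded outer and inner
    surface height maps.

    The outer surface map (first bone index from z=0) is opened and the
    inner surface map (last bone index) is closed with a flat disc of the
    closing radius.  A flat structuring element preserves linear ramps and
    gently curved plates exactly, so indentations narrower than the disc are
    lidded over at the level of the surrounding surface — without the sag a
    rolling ball leaves over a wide pit mouth.
    """
    nz = mask.shape[0]
    sentinel = nz + int(np.ceil(r_vox)) + 2
    any_bone = mask.any(axis=0)
    zt = np.where(any_bone, np.argmax(mask, axis=0), sentinel).astype(np.float64)
    zb = np.where(
        any_bone, nz - 1 - np.argmax(mask[::-1], axis=0), -sentinel
    ).astype(np.float64)
    fp = _disc_footprint(r_vox)
    zt_lid = ndi.grey_opening(zt, footprint=fp, mode="nearest")
    zb_lid = ndi.grey_closing(zb, footprint=fp, mode="nearest")
    zidx = np.arange(nz, dtype=np.float64)[:, None, None]
    return mask | ((zidx >= zt_lid[None]) & (zidx <= zb_lid[None]))


def close_and_fill(
    bone: BinaryMask, roi: BinaryMask, closing_radius_um: float
) -> BinaryMask:
    """Ball-closing of (bone AND roi) followed by cavity filling.

    Three filling mechanisms combine to reconstruct the intact plate:

    1. morphological closing by a discrete Euclidean ball of the given
       physical radius (computed via exact distance transforms; the volume
       is padded by the ball radius so border behaviour is as if background
       extended outward);
    2. filling of background cavities fully enclosed in 3D (6-connected
       background, the standard complement of 26-connected foreground);
    3. a height-field lid fill (:func:`_lid_fill`) that closes surface
       indentations of the plate at the level of the surrounding surface.

    The result contains its input (extensivity) and is a fixed point of the
    operation (idempotence on its own output).
    """
    require_same_grid(bone, roi)
    r_vox = closing_radius_um / bone.voxel_size_um
    if r_vox < 1.0:
        raise ValueError(
            f"closing radius {closing_radius_um} μm is smaller than one voxel"
        )
    pad = int(np.ceil(r_vox)) + 1
    m = np.pad(bone.data & roi.data, pad)
    dist_to_bone = ndi.distance_transform_edt(~m)
    dilated = dist_to_bone <= r_vox
    dist_to_outside = ndi.distance_transform_edt(dilated)
    closed = dist_to_outside > r_vox
    filled = ndi.binary_fill_holes(closed, structure=_BG_STRUCTURE)
    filled = _lid_fill(filled, r_vox)
    out = filled[pad:-pad, pad:-pad, pad:-pad]
    return BinaryMask.like(bone, out)


def extract_pit_fill(
    filled: BinaryMask, bone: BinaryMask, roi: BinaryMask
) -> BinaryMask:
    """Subtract the original bone from the closed-and-filled ROI, leaving
    the filled pit renderings: ``filled AND NOT bone AND roi``."""
    require_same_grid(filled, bone)
    require_same_grid(filled, roi)
    inside = bone.data & roi.data
    if np.any(inside & ~filled.data):
        raise ValueError("precondition violated: filled mask does not contain bone∧roi")
    return BinaryMask.like(filled, filled.data & ~bone.data & roi.data)


def _background_context(
    bone_data: np.ndarray, pit_data: np.ndarray
) -> tuple[np.ndarray, set[int], set[int]]:
    """Label the non-bone, non-candidate background (6-connected) and
    identify which labels touch the outer (z=0) and inner (z=max) faces."""
    bg = ~bone_data & ~pit_data
    labels, _ = ndi.label(bg, structure=_BG_STRUCTURE)
    outer_ids = set(np.unique(labels[0])) - {0}
    inner_ids = set(np.unique(labels[-1])) - {0}
    return labels, outer_ids, inner_ids


def _classify(
    component: np.ndarray,
    bg_labels: np.ndarray,
    outer_ids: set[int],
    inner_ids: set[int],
) -> str:
    dil = ndi.binary_dilation(component, structure=connectivity_structure(26))
    touched = set(np.unique(bg_labels[dil & (bg_labels > 0)]))
    touches_outer = bool(touched & outer_ids)
    touches_inner = bool(touched & inner_ids)
    if touches_outer and touches_inner:
        return "through"
    if touches_outer:
        return "outer"
    if touches_inner:
        return "inner"
    return "internal"


def classify_surface(
    component: BinaryMask, bone: BinaryMask, pit_mask: BinaryMask | None = None
) -> str:
    """Classify a pit-fill component by which plate surface it opens onto.

    The component is dilated by one voxel and tested against the background
    (non-bone) regions connected to the z=0 face (outer surface) and the
    z=max face (inner surface): outer only -> "outer", inner only ->
    "inner", both -> "through", neither -> "internal".  When other carved
    candidates exist, pass the full ``pit_mask`` so channels do not bridge
    the outer and inner backgrounds.
    """
    require_same_grid(component, bone)
    if np.any(component.data & bone.data):
        raise ValueError("component must be disjoint from bone")
    pit_data = component.data if pit_mask is None else pit_mask.data
    labels, outer_ids, inner_ids = _background_context(bone.data, pit_data)
    return _classify(component.data, labels, outer_ids, inner_ids)


def _expand_bbox(sl: tuple[slice, ...], shape: tuple[int, ...], margin: int = 1):
    return tuple(
        slice(max(0, s.start - margin), min(n, s.stop + margin))
        for s, n in zip(sl, shape)
    )


def label_candidates(
    pit_mask: BinaryMask,
    bone: BinaryMask,
    min_volume_um3: float = 0.0,
    connectivity: int = 26,
    roi: BinaryMask | None = None,
) -> list[PitCandidate]:
    """Connected components of the pit-fill mask, volume-filtered, ordered,
    and classified by surface.

    Components smaller than ``min_volume_um3`` are dropped (they still count
    as background separators for surface classification).  If ``roi`` is
    given, candidates adjacent to voxels outside it (or clipped by the
    lateral volume border) are flagged ``touches_roi_boundary``.
    """
    require_same_grid(pit_mask, bone)
    if np.any(pit_mask.data & bone.data):
        raise ValueError("pit mask must be disjoint from bone")
    structure = connectivity_structure(connectivity)
    labels, n = ndi.label(pit_mask.data, structure=structure)
    if n == 0:
        return []
    vox3 = pit_mask.voxel_volume_um3
    objects = ndi.find_objects(labels)
    bg_labels, outer_ids, inner_ids = _background_context(bone.data, pit_mask.data)
    shape = pit_mask.data.shape

    records = []
    for cid in range(1, n + 1):
        sl = _expand_bbox(objects[cid - 1], shape)
        comp = labels[sl] == cid
        count = int(comp.sum())
        if count * vox3 < min_volume_um3:
            continue
        idx = np.argwhere(comp)
        centroid = tuple(float(c) for c in idx.mean(axis=0) + [s.start for s in sl])
        surface = _classify(comp, bg_labels[sl], outer_ids, inner_ids)
        touches = False
        if roi is not None:
            dil = ndi.binary_dilation(comp, structure=structure)
            touches = bool(np.any(dil & ~roi.data[sl]))
        obj = objects[cid - 1]
        # lateral volume border counts as a boundary too
        if obj[1].start == 0 or obj[1].stop == shape[1] or obj[2].start == 0 or obj[2].stop == shape[2]:
            touches = True
        bbox = (
            obj[0].start, obj[0].stop, obj[1].start, obj[1].stop, obj[2].start, obj[2].stop,
        )
        records.append((count, centroid, bbox, surface, touches))

    records.sort(key=lambda r: (-r[0], r[1]))
    return [
        PitCandidate(
            pit_id=i + 1,
            voxel_count=count,
            volume_um3=count * vox3,
            centroid_voxel=centroid,
            bbox=bbox,
            surface_class=surface,
            touches_roi_boundary=touches,
        )
        for i, (count, centroid, bbox, surface, touches) in enumerate(records)
    ]


def set_status(candidate: PitCandidate, status: str) -> PitCandidate:
    if status not in ("candidate", "confirmed", "rejected"):
        raise ValueError(f"unknown status {status!r}")
    return replace(candidate, status=status)
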