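"""Pit review: distinguishing resorption pits from natural porosity.

The assay's confirmation step is reproduced headlessly through an editable
CSV manifest: every candidate gets a row with its measurements and a
prefilled decision (accept for outer-surface concavities, reject for
through-channels, inner-surface and internal features).  A human can edit
the decision column and re-apply; ``auto_review`` applies the prefill policy
unchanged for unattended runs.  Optional per-pit PNG montages of three
orthogonal maximum projections support manual calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pits import PitCandidate, set_status
from .volio import VoxelVolume

MANIFEST_COLUMNS = (
    "pit_id",
    "voxel_count",
    "volume_um3",
    "centroid_z",
    "centroid_y",
    "centroid_x",
    "surface_class",
    "touches_roi_boundary",
    "decision",
    "reason",
)


@dataclass(frozen=True)
class ReviewDecision:
    pit_id: int
    decision: str  # "accept" | "reject"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.decision not in ("accept", "reject"):
            raise ValueError(f"decision must be accept/reject, got {self.decision!r}")


def _default_decision(candidate: PitCandidate) -> ReviewDecision:
    if candidate.surface_class == "outer":
        return ReviewDecision(candidate.pit_id, "accept", "outer-surface concavity")
    return ReviewDecision(
        candidate.pit_id, "reject", f"{candidate.surface_class} feature"
    )


def auto_review(candidates: Sequence[PitCandidate]) -> list[ReviewDecision]:
    """Deterministic policy: accept iff the fill opens onto the outer
    calvarial surface only."""
    return [_default_decision(c) for c in candidates]


def init_manifest(candidates: Sequence[PitCandidate], path: str | Path) -> None:
    """Write the review manifest CSV with prefilled decisions."""
    rows = []
    for c, d in zip(candidates, auto_review(candidates)):
        rows.append(
            {
                "pit_id": c.pit_id,
                "voxel_count": c.voxel_count,
                "volume_um3": c.volume_um3,
                "centroid_z": c.centroid_voxel[0],
                "centroid_y": c.centroid_voxel[1],
                "centroid_x": c.centroid_voxel[2],
                "surface_class": c.surface_class,
                "touches_roi_boundary": c.touches_roi_boundary,
                "decision": d.decision,
                "reason": d.reason,
            }
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[ReviewDecision]:
    df = pd.read_csv(path)
    missing = {"pit_id", "decision"} - set(df.columns)
    if missing:
        raise ValueError(f"malformed manifest, missing columns: {sorted(missing)}")
    ids = df["pit_id"].tolist()
    if len(ids) != len(set(ids)):
        raise ValueError("manifest contains duplicate pit_ids")
    return [
        ReviewDecision(
            pit_id=int(r["pit_id"]),
            decision=str(r["decision"]),
            reason="" if pd.isna(r.get("reason")) else str(r.get("reason")),
        )
        for r in df.to_dict("records")
    ]


def apply_decisions(
    candidates: Sequence[PitCandidate], decisions: Sequence[ReviewDecision]
) -> list[PitCandidate]:
    """Set each candidate's status from its decision; order preserved.  Every
    candidate must have exactly one decision."""
    by_id = {}
    for d in decisions:
        if d.pit_id in by_id:
            raise ValueError(f"duplicate decision for pit_id {d.pit_id}")
        by_id[d.pit_id] = d
    known = {c.pit_id for c in candidates}
    unknown = set(by_id) - known
    if unknown:
        raise ValueError(f"decisions reference unknown pit_ids: {sorted(unknown)}")
    out = []
    for c in candidates:
        if c.pit_id not in by_id:
            raise ValueError(f"missing decision for pit_id {c.pit_id}")
        status = "confirmed" if by_id[c.pit_id].decision == "accept" else "rejected"
        out.append(set_status(c, status))
    return out


def confirmed(candidates: Sequence[PitCandidate]) -> list[PitCandidate]:
    return [c for c in candidates if c.status == "confirmed"]


def save_pit_montages(
    vol: VoxelVolume, candidates: Sequence[PitCandidate], out_dir: str | Path
) -> list[Path]:
    """Emit one PNG per candidate: maximum projections of the bounding box
    (padded by 4 voxels) along each axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in candidates:
        z0, z1, y0, y1, x0, x1 = c.bbox
        pad = 4
        crop = vol.data[
            max(0, z0 - pad) : z1 + pad,
            max(0, y0 - pad) : y1 + pad,
            max(0, x0 - pad) : x1 + pad,
        ]
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        for ax, axis, title in zip(axes, (0, 1, 2), ("z (axial)", "y", "x")):
            ax.imshow(crop.max(axis=axis), cmap="gray")
            ax.set_title(f"pit {c.pit_id}: max proj {title}", fontsize=8)
            ax.axis("off")
        path = out_dir / f"pit_{c.pit_id:03d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
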