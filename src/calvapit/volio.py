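"""Volume, mask and results-table I/O, plus the package's grid conventions.

Every 3D grid in calvapit uses axis order ``(z, y, x)`` with ``z`` the
scan/plate-normal axis, 0-based indices, and isotropic voxels of edge length
``voxel_size_um`` (micrometres).  Voxel *centers* sit at
``origin_um + index * voxel_size_um``.  The only unit conversion anywhere in
the package is ``volume_um3 = voxel_count * voxel_size_um ** 3``.

Supported on-disk formats: multi-page TIFF, a directory of equally sized 2D
TIFF slices (lexicographic name order = ascending z), and NRRD / MetaImage
via SimpleITK.  TIFF carries no trustworthy spacing metadata, so a voxel size
must always be given when reading TIFF; NRRD/MetaImage spacing is honoured
and cross-checked against any explicitly supplied value.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

TREATMENTS = ("pristine", "vehicle", "rankl", "rankl_za", "other")
SEXES = ("M", "F", "unknown")

RESULTS_COLUMNS = (
    "sample_id",
    "treatment",
    "sex",
    "pit_count",
    "total_volume_um3",
    "mean_pit_volume_um3",
)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_ITK_SUFFIXES = {".nrrd", ".mhd", ".mha"}


def _check_grid(data: np.ndarray, voxel_size_um: float) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError("all three dimensions must be >= 1")
    if not (voxel_size_um > 0 and math.isfinite(voxel_size_um)):
        raise ValueError(f"voxel_size_um must be positive, got {voxel_size_um}")


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D grayscale image grid with isotropic physical voxel size in μm."""

    data: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        _check_grid(self.data, self.voxel_size_um)
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensity values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid co-registered to a :class:`VoxelVolume`."""

    data: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        _check_grid(self.data, self.voxel_size_um)
        if self.data.dtype != np.bool_:
            raise ValueError(f"mask data must be boolean, got {self.data.dtype}")

    @classmethod
    def like(cls, parent: "VoxelVolume | BinaryMask", data: np.ndarray) -> "BinaryMask":
        if data.shape != parent.data.shape:
            raise ValueError("mask shape must match its parent grid")
        return cls(np.asarray(data, dtype=bool), parent.voxel_size_um, parent.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def count(self) -> int:
        return int(self.data.sum())

    def volume_um3(self) -> float:
        return self.count() * self.voxel_volume_um3


def require_same_grid(a: VoxelVolume | BinaryMask, b: VoxelVolume | BinaryMask) -> None:
    """Raise unless *a* and *b* share shape and voxel size."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"grid shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not math.isclose(a.voxel_size_um, b.voxel_size_um, rel_tol=1e-9):
        raise ValueError(
            f"voxel size mismatch: {a.voxel_size_um} vs {b.voxel_size_um}"
        )


# ---------------------------------------------------------------------------
# volume / mask readers and writers


def _reconcile_voxel_size(meta: float | None, arg: float | None) -> float:
    if meta is None and arg is None:
        raise ValueError("voxel size required: format carries no spacing metadata")
    if meta is not None and arg is not None:
        if not math.isclose(meta, arg, rel_tol=1e-6):
            raise ValueError(
                f"conflicting voxel size: metadata {meta} μm vs argument {arg} μm"
            )
        return float(meta)
    return float(meta if meta is not None else arg)


def _read_itk(path: Path) -> tuple[np.ndarray, float]:
    import SimpleITK as sitk  # optional heavyweight import

    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()  # (x, y, z)
    if not all(math.isclose(s, spacing[0], rel_tol=1e-6) for s in spacing):
        raise ValueError(f"anisotropic voxels are not supported: spacing {spacing}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return arr, float(spacing[0])


def _read_slice_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no TIFF slices found in directory {path}")
    slices = []
    for f in files:
        sl = tifffile.imread(f)
        if sl.ndim != 2:
            raise ValueError(f"slice {f.name} is not a 2D image")
        if slices and sl.shape != slices[0].shape:
            raise ValueError(
                f"inconsistent slice shapes: {f.name} is {sl.shape}, "
                f"expected {slices[0].shape}"
            )
        slices.append(sl)
    return np.stack(slices, axis=0)


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> VoxelVolume:
    """Read a grayscale volume from TIFF (multi-page or slice directory),
    NRRD or MetaImage.

    ``voxel_size_um`` is mandatory for TIFF input.  For NRRD/MetaImage the
    stored spacing is used; supplying a conflicting value is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    meta_spacing: float | None = None
    if path.is_dir():
        arr = _read_slice_dir(path)
    elif path.suffix.lower() in _ITK_SUFFIXES:
        arr, meta_spacing = _read_itk(path)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF, got ndim={arr.ndim}")
    else:
        raise ValueError(f"unrecognized volume format: {path.suffix!r}")
    vs = _reconcile_voxel_size(meta_spacing, voxel_size_um)
    return VoxelVolume(arr, vs)


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume losslessly; format chosen from the file suffix."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() in _ITK_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.data)
        img.SetSpacing((vol.voxel_size_um,) * 3)
        sitk.WriteImage(img, str(path))
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, vol.data)
    else:
        raise ValueError(f"unrecognized volume format: {path.suffix!r}")


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit {0, 255} volume."""
    as_u8 = np.where(mask.data, np.uint8(255), np.uint8(0))
    write_volume(VoxelVolume(as_u8, mask.voxel_size_um, mask.origin_um), path)


def read_mask(path: str | Path, voxel_size_um: float | None = None) -> BinaryMask:
    vol = read_volume(path, voxel_size_um)
    return BinaryMask(vol.data > 0, vol.voxel_size_um, vol.origin_um)


# ---------------------------------------------------------------------------
# per-animal results rows


@dataclass(frozen=True)
class ResultsRow:
    """One animal's pit volumetry summary (one row of the results CSV)."""

    sample_id: str
    treatment: str
    sex: str
    pit_count: int
    total_volume_um3: float
    mean_pit_volume_um3: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.pit_count < 0 or self.total_volume_um3 < 0:
            raise ValueError("pit_count and total_volume_um3 must be non-negative")
        if self.pit_count == 0:
            if self.mean_pit_volume_um3 != 0:
                raise ValueError("mean pit volume must be 0 when pit_count is 0")
        else:
            expect = self.total_volume_um3 / self.pit_count
            if not math.isclose(self.mean_pit_volume_um3, expect, rel_tol=1e-9):
                raise ValueError(
                    "mean_pit_volume_um3 inconsistent with total/count "
                    f"({self.mean_pit_volume_um3} vs {expect})"
                )


def write_results(rows: Sequence[ResultsRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [dataclasses.asdict(r) for r in rows], columns=list(RESULTS_COLUMNS)
    )
    # %.17g guarantees bit-exact float64 round-trips through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> list[ResultsRow]:
    """Read a results CSV.  Rows with an unrecognized treatment level are
    kept with ``treatment="other"`` and a warning."""
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    missing = set(RESULTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed results CSV, missing columns: {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        if rec["treatment"] not in TREATMENTS:
            warnings.warn(
                f"unknown treatment {rec['treatment']!r} for sample "
                f"{rec['sample_id']!r}; keeping row with treatment='other'",
                stacklevel=2,
            )
            rec["treatment"] = "other"
        rows.append(
            ResultsRow(
                sample_id=str(rec["sample_id"]),
                treatment=str(rec["treatment"]),
                sex=str(rec["sex"]),
                pit_count=int(rec["pit_count"]),
                total_volume_um3=float(rec["total_volume_um3"]),
                mean_pit_volume_um3=float(rec["mean_pit_volume_um3"]),
            )
        )
    return rows
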