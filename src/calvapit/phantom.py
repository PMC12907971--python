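"""Synthetic calvaria phantom with planted resorption pits and porosity.

The phantom emulates the imaging target of the calvarial resorption assay:
a thin, gently domed bone plate (the skull roof of a juvenile mouse) bearing

* surface indentations carved as spherical caps — stand-ins for osteoclast
  resorption pits, chosen because the cap has a closed-form volume
  ``pi * h^2 * (3 r - h) / 3`` that serves as analytic ground truth, and
* narrow through-going channels — stand-ins for vascular/natural porosity
  that the review step must exclude from volumetry.

The clean plate (bone intensity vs background intensity) is degraded by a
Gaussian blur (a partial-volume proxy) followed by additive i.i.d. Gaussian
noise.  Everything is deterministic for a fixed spec + seed, and the returned
:class:`PhantomTruth` records the exact voxelized volume of every carved
defect, so recovery by the analysis pipeline can be scored without any
reference scan.

Geometry conventions: the outer calvarial surface faces the z = 0 face of
the volume; the outer surface height is ``s(y, x) = z0 + sag * rho_hat^2``,
a shallow paraboloid, and bone occupies ``s <= z < s + thickness``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .volio import VoxelVolume

THROUGH_CHANNEL = "through_channel"
INTERNAL_PORE = "internal_pore"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic plate and its degradation model."""

    shape: tuple[int, int, int] = (60, 256, 256)
    voxel_size_um: float = 7.5
    plate_thickness_um: float = 150.0
    plate_curvature: float = 40.0  # paraboloid sag of the outer surface, μm
    bone_intensity: float = 200.0
    background_intensity: float = 50.0
    noise_sd: float = 15.0
    blur_sigma_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be three positive integers")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.plate_thickness_um < 3 * self.voxel_size_um:
            raise ValueError("plate thickness must be at least 3 voxels")
        if self.plate_curvature < 0 or self.noise_sd < 0 or self.blur_sigma_um < 0:
            raise ValueError("curvature, noise_sd and blur_sigma_um must be >= 0")
        if not self.bone_intensity > self.background_intensity:
            raise ValueError("bone_intensity must exceed background_intensity")


@dataclass(frozen=True)
class PlantedPit:
    """Ground-truth record of one carved spherical-cap pit.

    ``center_um`` is the point on the outer bone surface above the cap;
    the carving sphere has radius ``cap_radius_um`` and indents the plate
    by ``cap_depth_um``.
    """

    center_um: tuple[float, float, float]
    cap_radius_um: float
    cap_depth_um: float
    analytic_volume_um3: float
    voxelized_volume_um3: float


@dataclass(frozen=True)
class PorosityFeature:
    """A natural-porosity defect: a z-aligned through channel or an
    internal pore (a sphere touching neither surface)."""

    center_um: tuple[float, float, float]
    channel_radius_um: float
    kind: str = THROUGH_CHANNEL

    def __post_init__(self) -> None:
        if self.kind not in (THROUGH_CHANNEL, INTERNAL_PORE):
            raise ValueError(f"unknown porosity kind {self.kind!r}")
        if self.channel_radius_um <= 0:
            raise ValueError("channel_radius_um must be positive")


@dataclass(frozen=True)
class PhantomTruth:
    pits: tuple[PlantedPit, ...]
    porosity: tuple[PorosityFeature, ...]
    spec: PhantomSpec

    def to_dict(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "pits": [dataclasses.asdict(p) for p in self.pits],
            "porosity": [dataclasses.asdict(p) for p in self.porosity],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        spec_d = dict(d["spec"])
        spec_d["shape"] = tuple(spec_d["shape"])
        return cls(
            pits=tuple(
                PlantedPit(**{**p, "center_um": tuple(p["center_um"])})
                for p in d["pits"]
            ),
            porosity=tuple(
                PorosityFeature(**{**p, "center_um": tuple(p["center_um"])})
                for p in d["porosity"]
            ),
            spec=PhantomSpec(**spec_d),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load_json(cls, path: str | Path) -> "PhantomTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def spherical_cap_volume(r: float, h: float) -> float:
    """Volume of a spherical cap of sphere radius *r* and height *h*:
    ``pi * h^2 * (3 r - h) / 3``."""
    if r <= 0:
        raise ValueError("cap sphere radius must be positive")
    if not 0 <= h <= r:
        raise ValueError(f"cap height must satisfy 0 <= h <= r, got h={h}, r={r}")
    return math.pi * h * h * (3.0 * r - h) / 3.0


# ---------------------------------------------------------------------------
# plate geometry


def _surface_um(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Outer-surface height map s(y, x) in μm and its base offset z0."""
    nz, ny, nx = spec.shape
    vs = spec.voxel_size_um
    lz = nz * vs
    cy, cx = (ny - 1) / 2.0 * vs, (nx - 1) / 2.0 * vs
    half = min(ny, nx) / 2.0 * vs
    yy = (np.arange(ny) * vs - cy) / half
    xx = (np.arange(nx) * vs - cx) / half
    rho2 = yy[:, None] ** 2 + xx[None, :] ** 2
    max_sag = spec.plate_curvature * float(rho2.max()) if spec.plate_curvature else 0.0
    z0 = (lz - spec.plate_thickness_um - max_sag) / 2.0
    if z0 < 2 * vs:
        raise ValueError("volume too thin in z for the requested plate and curvature")
    return z0 + spec.plate_curvature * rho2, z0


def _surface_at(spec: PhantomSpec, y_um: float, x_um: float) -> float:
    vs = spec.voxel_size_um
    _, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0 * vs, (nx - 1) / 2.0 * vs
    half = min(ny, nx) / 2.0 * vs
    rho2 = ((y_um - cy) / half) ** 2 + ((x_um - cx) / half) ** 2
    nzv = spec.shape[0] * vs
    yy = (np.array([0, ny - 1]) * vs - cy) / half  # corner sag, matching _surface_um
    xx = (np.array([0, nx - 1]) * vs - cx) / half
    max_sag = spec.plate_curvature * float(
        (yy[:, None] ** 2 + xx[None, :] ** 2).max()
    )
    z0 = (nzv - spec.plate_thickness_um - max_sag) / 2.0
    return z0 + spec.plate_curvature * rho2


def plate_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the intact (defect-free) plate."""
    surface, _ = _surface_um(spec)
    nz = spec.shape[0]
    z_um = np.arange(nz) * spec.voxel_size_um
    # bone occupies the half-open physical slab [s, s + T)
    above = z_um[:, None, None] >= surface[None, :, :]
    below = z_um[:, None, None] < (surface + spec.plate_thickness_um)[None, :, :]
    return above & below


# ---------------------------------------------------------------------------
# phantom generation


def _pit_bounding_sphere(
    spec: PhantomSpec, y: float, x: float, r: float, h: float
) -> tuple[np.ndarray, float]:
    s = _surface_at(spec, y, x)
    return np.array([s - (r - h), y, x]), r


def _porosity_bounding_sphere(
    spec: PhantomSpec, feat: PorosityFeature
) -> tuple[np.ndarray, float]:
    if feat.kind == THROUGH_CHANNEL:
        _, y, x = feat.center_um
        s = _surface_at(spec, y, x)
        half_t = spec.plate_thickness_um / 2.0
        return (
            np.array([s + half_t, y, x]),
            math.hypot(half_t, feat.channel_radius_um),
        )
    return np.asarray(feat.center_um, dtype=float), feat.channel_radius_um


def generate_phantom(
    spec: PhantomSpec,
    pits: Sequence[tuple[float, float, float, float]] = (),
    porosity: Sequence[PorosityFeature] = (),
) -> tuple[VoxelVolume, PhantomTruth]:
    """Build the phantom volume and its ground truth.

    ``pits`` are ``(y_um, x_um, cap_radius_um, cap_depth_um)`` tuples; each
    pit is carved as the intersection of the plate with a sphere placed so
    the cap indents the outer surface by ``cap_depth_um``.  Through channels
    are carved as z-aligned cylinders spanning the plate.  Defects whose
    bounding spheres intersect are rejected so per-defect truth volumes stay
    unambiguous.
    """
    vs = spec.voxel_size_um
    nz, ny, nx = spec.shape
    surface, _ = _surface_um(spec)
    plate = plate_mask(spec)
    bone = plate.copy()
    vox_vol = vs**3

    bounding: list[tuple[np.ndarray, float]] = []
    for (y, x, r, h) in pits:
        if h > r:
            raise ValueError(f"pit depth {h} exceeds cap sphere radius {r}")
        if h >= spec.plate_thickness_um:
            raise ValueError(
                f"pit depth {h} μm would perforate the "
                f"{spec.plate_thickness_um} μm plate"
            )
        if not (0 <= y <= (ny - 1) * vs and 0 <= x <= (nx - 1) * vs):
            raise ValueError(f"pit center ({y}, {x}) outside the field")
        bounding.append(_pit_bounding_sphere(spec, y, x, r, h))
    for feat in porosity:
        bounding.append(_porosity_bounding_sphere(spec, feat))
    for i in range(len(bounding)):
        for j in range(i + 1, len(bounding)):
            (ci, ri), (cj, rj) = bounding[i], bounding[j]
            if float(np.linalg.norm(ci - cj)) < ri + rj:
                raise ValueError(
                    f"overlapping defects: bounding spheres {i} and {j} intersect"
                )

    z_um = np.arange(nz) * vs
    y_um = np.arange(ny) * vs
    x_um = np.arange(nx) * vs

    truth_pits: list[PlantedPit] = []
    for (y, x, r, h) in pits:
        s_local = _surface_at(spec, y, x)
        center = np.array([s_local - (r - h), y, x])
        # carve only within the sphere's bounding box for speed
        iz = slice(
            max(0, int((center[0] - r) / vs) - 1), min(nz, int((center[0] + r) / vs) + 2)
        )
        iy = slice(max(0, int((y - r) / vs) - 1), min(ny, int((y + r) / vs) + 2))
        ix = slice(max(0, int((x - r) / vs) - 1), min(nx, int((x + r) / vs) + 2))
        dz = z_um[iz] - center[0]
        dy = y_um[iy] - center[1]
        dx = x_um[ix] - center[2]
        inside = (
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
            <= r**2
        )
        carved = plate[iz, iy, ix] & inside
        bone[iz, iy, ix] &= ~carved
        truth_pits.append(
            PlantedPit(
                center_um=(float(s_local), float(y), float(x)),
                cap_radius_um=float(r),
                cap_depth_um=float(h),
                analytic_volume_um3=spherical_cap_volume(r, h),
                voxelized_volume_um3=float(carved.sum()) * vox_vol,
            )
        )

    truth_porosity: list[PorosityFeature] = []
    for feat in porosity:
        _, y, x = feat.center_um
        cr = feat.channel_radius_um
        if feat.kind == THROUGH_CHANNEL:
            disc = (y_um[:, None] - y) ** 2 + (x_um[None, :] - x) ** 2 <= cr**2
            bone &= ~disc[None, :, :]
            s_local = _surface_at(spec, y, x)
            recorded = PorosityFeature(
                center_um=(float(s_local + spec.plate_thickness_um / 2), y, x),
                channel_radius_um=cr,
                kind=feat.kind,
            )
        else:
            cz = feat.center_um[0]
            s_local = _surface_at(spec, y, x)
            if not (
                s_local + vs < cz - cr and cz + cr < s_local + spec.plate_thickness_um - vs
            ):
                raise ValueError("internal pore must touch neither plate surface")
            dz = z_um[:, None, None] - cz
            dy = y_um[None, :, None] - y
            dx = x_um[None, None, :] - x
            bone &= ~(dz**2 + dy**2 + dx**2 <= cr**2)
            recorded = feat
        truth_porosity.append(recorded)

    clean = np.where(bone, spec.bone_intensity, spec.background_intensity).astype(
        np.float64
    )
    if spec.blur_sigma_um > 0:
        clean = ndi.gaussian_filter(clean, sigma=spec.blur_sigma_um / vs)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)

    vol = VoxelVolume(clean, vs)
    truth = PhantomTruth(tuple(truth_pits), tuple(truth_porosity), spec)
    return vol, truth


# ---------------------------------------------------------------------------
# default study phantom

_PIT_RADII_UM = (40.0, 45.0, 50.0, 55.0, 60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 115.0, 120.0)
_PIT_SLOTS_UM = tuple(
    (y, x) for y in (320.0, 960.0, 1600.0) for x in (240.0, 720.0, 1200.0, 1680.0)
)
_CHANNEL_SLOTS_UM = tuple(
    (y, x) for y in (640.0, 1280.0) for x in (480.0, 960.0, 1440.0)
)
_CHANNEL_RADIUS_UM = 15.0


def default_phantom(
    seed: int, n_pits: int = 12, n_channels: int = 6
) -> tuple[VoxelVolume, PhantomTruth]:
    """The reference study phantom: a 256x256x60 grid at 7.5 μm with a
    ~150 μm domed plate, 12 hemispherical pits of sphere radius 40–120 μm on
    a jittered grid, and 6 through channels of radius 15 μm.  Contrast and
    noise give SNR ~ 10.  Deterministic per seed.
    """
    if not 0 <= n_pits <= 12:
        raise ValueError("n_pits must be between 0 and 12")
    if not 0 <= n_channels <= 6:
        raise ValueError("n_channels must be between 0 and 6")
    spec = PhantomSpec(seed=seed)
    layout_rng = np.random.default_rng([seed, 0x5EED])
    radii = layout_rng.permutation(np.array(_PIT_RADII_UM))[:n_pits]
    pits = []
    for (y, x), r in zip(_PIT_SLOTS_UM[:n_pits], radii):
        jy, jx = layout_rng.uniform(-22.5, 22.5, size=2)
        pits.append((y + jy, x + jx, float(r), float(r)))  # hemispherical caps
    porosity = []
    for (y, x) in _CHANNEL_SLOTS_UM[:n_channels]:
        jy, jx = layout_rng.uniform(-15.0, 15.0, size=2)
        porosity.append(
            PorosityFeature(
                center_um=(0.0, y + jy, x + jx),
                channel_radius_um=_CHANNEL_RADIUS_UM,
                kind=THROUGH_CHANNEL,
            )
        )
    return generate_phantom(spec, pits, porosity)
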