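"""Synthetic skin-OCT phantom with voxel-level ground truth.

The phantom emulates the contrast mechanisms that skin OCT angiography and
lymphangiography rely on:

* fully developed speckle — each voxel carries a circular complex Gaussian
  field whose expected intensity is set by the local tissue amplitude;
* a layered medium — a brighter epidermis above a dermis, separated by the
  epidermal--dermal junction (EDJ), under an optionally wavy surface;
* round-trip light attenuation — intensity decays as exp(-2 mu z) with
  depth measured from the local surface;
* lymphatic lumens — tubes of strongly reduced scattering (dark in the
  structural image but static across repeats);
* blood vessels — tubes whose speckle decorrelates between repeated
  B-frames (dynamic speckle), the contrast OMAG differencing detects;
* optional global axial bulk motion per repeated frame, and an additive
  complex noise floor.

Because the geometry is analytic, the generator also returns a
:class:`PhantomGroundTruth` with voxel masks and layer maps, which serves
as the oracle for every downstream processing stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .volume_io import RepeatedBScanVolume, ScanProtocol

__all__ = [
    "Tube",
    "PhantomSpec",
    "PhantomGroundTruth",
    "default_spec",
    "generate_phantom",
    "analytic_tube_volume_fraction",
    "analytic_projected_area_fraction",
    "project_mask_to_slab",
]


@dataclass(frozen=True)
class Tube:
    """A tubular inclusion defined by a centerline polyline and a radius.

    ``points`` are (z, x, y) voxel coordinates (floats allowed); the tube is
    the set of voxels whose physical distance to the polyline is at most
    ``radius_um``.  Distances are computed in micrometres, so tubes are
    ellipses in (anisotropic) voxel space.
    """

    points: Tuple[Tuple[float, float, float], ...]
    radius_um: float

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("tube centerline needs at least 2 points")
        if not self.radius_um > 0:
            raise ValueError(f"tube radius must be > 0, got {self.radius_um}")

    def length_um(self, axial_pitch_um: float, lateral_pitch_um: float) -> float:
        scale = np.array([axial_pitch_um, lateral_pitch_um, lateral_pitch_um])
        pts = np.asarray(self.points, dtype=float) * scale
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and acquisition parameters of the digital phantom.

    Defaults model a ~1 mm deep, 2.56 x 2.56 mm patch of forearm-like skin
    sampled at 8 um axial and 20 um lateral pitch with 8 repeated B-frames
    per location.
    """

    nz: int = 128
    nx: int = 128
    ny: int = 128
    axial_pitch_um: float = 8.0
    lateral_pitch_um: float = 20.0
    dermis_amplitude: float = 1.0
    epidermis_multiplier: float = 2.0
    epidermis_thickness_um: float = 120.0
    attenuation_per_mm: float = 1.5
    surface_depth_um: float = 160.0
    topography_amplitude_um: float = 16.0
    topography_period_mm: float = 1.28
    lymph_tubes: Tuple[Tube, ...] = ()
    lymph_amplitude_scale: float = 0.1
    blood_tubes: Tuple[Tube, ...] = ()
    blood_decorrelation: float = 1.0
    n_repeats: int = 8
    bulk_shifts: Optional[Tuple[int, ...]] = None
    noise_sigma: float = 0.02
    frame_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if min(self.nz, self.nx, self.ny) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.blood_tubes and self.n_repeats < 2:
            raise ValueError(
                "blood tubes need n_repeats >= 2: flow contrast is defined "
                "by differences between repeated frames"
            )
        if not (0.0 <= self.lymph_amplitude_scale < 1.0):
            raise ValueError("lymph_amplitude_scale must be in [0, 1)")
        if not (0.0 < self.blood_decorrelation <= 1.0):
            raise ValueError("blood_decorrelation must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.epidermis_multiplier <= 0:
            raise ValueError("epidermis_multiplier must be > 0")
        if self.bulk_shifts is not None and len(self.bulk_shifts) != self.n_repeats:
            raise ValueError(
                f"bulk_shifts must have one entry per repeat "
                f"({self.n_repeats}), got {len(self.bulk_shifts)}"
            )
        for tube in self.lymph_tubes + self.blood_tubes:
            self._check_tube_inside(tube)

    def _check_tube_inside(self, tube: Tube) -> None:
        rz = tube.radius_um / self.axial_pitch_um
        rl = tube.radius_um / self.lateral_pitch_um
        pts = np.asarray(tube.points, dtype=float)
        lo = pts.min(axis=0) - np.array([rz, rl, rl])
        hi = pts.max(axis=0) + np.array([rz, rl, rl])
        dims = np.array([self.nz, self.nx, self.ny], dtype=float)
        if (lo < -0.5).any() or (hi > dims - 0.5).any():
            raise ValueError(
                f"tube (radius {tube.radius_um} um) extends outside the "
                f"grid {tuple(int(d) for d in dims)}: bounds {lo} .. {hi}"
            )

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return (self.nz, self.nx, self.ny)

    def protocol(self) -> ScanProtocol:
        return ScanProtocol(
            fov_x_mm=self.nx * self.lateral_pitch_um / 1000.0,
            fov_y_mm=self.ny * self.lateral_pitch_um / 1000.0,
            n_alines=self.nx,
            n_locations=self.ny,
            n_repeats=self.n_repeats,
            frame_rate_hz=self.frame_rate_hz,
            axial_range_mm=self.nz * self.axial_pitch_um / 1000.0,
            axial_pitch_um=self.axial_pitch_um,
        )


@dataclass
class PhantomGroundTruth:
    """Voxel-level truth emitted with every phantom.

    ``lymph_mask`` and ``blood_mask`` are (z, x, y) booleans; ``surface_map``
    and ``edj_map`` are (x, y) depths in (fractional) voxels; ``bulk_shifts``
    are the injected per-repeat axial shifts in voxels.
    """

    lymph_mask: np.ndarray
    blood_mask: np.ndarray
    surface_map: np.ndarray
    edj_map: np.ndarray
    bulk_shifts: np.ndarray

    def __post_init__(self) -> None:
        if self.lymph_mask.shape != self.blood_mask.shape:
            raise ValueError("lymph and blood masks must share a shape")
        if (self.lymph_mask & self.blood_mask).any():
            raise ValueError("lymph and blood masks must be disjoint")
        if (self.edj_map < self.surface_map).any():
            raise ValueError("EDJ must be at or below the surface everywhere")


def default_spec(**overrides) -> PhantomSpec:
    """The default study phantom: three lymphatic lumens (one per standard
    dermal slab at 100, 300 and 500 um below the EDJ) and three blood
    vessels in the upper/mid dermis, in a 128^3 voxel grid.

    Tube lanes are laid out along the fast axis at distinct slow-axis
    positions so the lymph and blood masks are disjoint by construction.
    """
    lymph = (
        # 0-200 um slab: centered ~100 um below the EDJ (z~47)
        Tube(points=((47.0, 6.0, 30.0), (47.0, 121.0, 30.0)), radius_um=60.0),
        # 200-400 um slab: ~300 um below EDJ (z~72), gentle diagonal
        Tube(points=((72.0, 6.0, 60.0), (72.0, 121.0, 68.0)), radius_um=60.0),
        # 400-600 um slab: ~500 um below EDJ (z~97), larger caliber
        Tube(points=((97.0, 6.0, 98.0), (97.0, 121.0, 98.0)), radius_um=70.0),
    )
    blood = (
        Tube(points=((50.0, 6.0, 14.0), (50.0, 121.0, 14.0)), radius_um=40.0),
        Tube(points=((55.0, 6.0, 44.0), (55.0, 121.0, 48.0)), radius_um=40.0),
        Tube(points=((75.0, 6.0, 112.0), (75.0, 121.0, 112.0)), radius_um=50.0),
    )
    spec = PhantomSpec(lymph_tubes=lymph, blood_tubes=blood)
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def _voxel_coords_um(spec: PhantomSpec):
    z = np.arange(spec.nz, dtype=np.float32) * spec.axial_pitch_um
    x = np.arange(spec.nx, dtype=np.float32) * spec.lateral_pitch_um
    y = np.arange(spec.ny, dtype=np.float32) * spec.lateral_pitch_um
    return z, x, y


def _rasterize_tubes(spec: PhantomSpec, tubes: Sequence[Tube]) -> np.ndarray:
    """Boolean (z, x, y) mask of all voxels within radius of any centerline.

    Each polyline segment is rasterized independently over its physical
    bounding box, which keeps the cost proportional to tube volume rather
    than grid volume.
    """
    mask = np.zeros(spec.grid_shape, dtype=bool)
    if not tubes:
        return mask
    zc, xc, yc = _voxel_coords_um(spec)
    scale = np.array(
        [spec.axial_pitch_um, spec.lateral_pitch_um, spec.lateral_pitch_um]
    )
    for tube in tubes:
        pts = np.asarray(tube.points, dtype=float) * scale  # physical um
        r = tube.radius_um
        for p0, p1 in zip(pts[:-1], pts[1:]):
            lo = np.minimum(p0, p1) - r - 1e-6
            hi = np.maximum(p0, p1) + r + 1e-6
            iz = np.searchsorted(zc, [lo[0], hi[0]])
            ix = np.searchsorted(xc, [lo[1], hi[1]])
            iy = np.searchsorted(yc, [lo[2], hi[2]])
            iz0, iz1 = max(iz[0] - 1, 0), min(iz[1] + 1, spec.nz)
            ix0, ix1 = max(ix[0] - 1, 0), min(ix[1] + 1, spec.nx)
            iy0, iy1 = max(iy[0] - 1, 0), min(iy[1] + 1, spec.ny)
            Z, X, Y = np.meshgrid(
                zc[iz0:iz1], xc[ix0:ix1], yc[iy0:iy1], indexing="ij"
            )
            d = np.stack([Z - p0[0], X - p0[1], Y - p0[2]], axis=-1)
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            if seg_len2 == 0.0:
                dist2 = (d * d).sum(axis=-1)
            else:
                t = np.clip((d @ seg) / seg_len2, 0.0, 1.0)
                closest = d - t[..., None] * seg[None, None, None, :]
                dist2 = (closest * closest).sum(axis=-1)
            mask[iz0:iz1, ix0:ix1, iy0:iy1] |= dist2 <= r * r
    return mask


def _surface_map(spec: PhantomSpec) -> np.ndarray:
    """(x, y) surface depth in fractional voxels, with sinusoidal topography."""
    x_um = np.arange(spec.nx, dtype=np.float64) * spec.lateral_pitch_um
    y_um = np.arange(spec.ny, dtype=np.float64) * spec.lateral_pitch_um
    base = spec.surface_depth_um
    if spec.topography_amplitude_um > 0:
        period = spec.topography_period_mm * 1000.0
        wav = np.sin(2 * np.pi * x_um / period)[:, None] * np.cos(
            2 * np.pi * y_um / period
        )[None, :]
        depth_um = base + spec.topography_amplitude_um * wav
    else:
        depth_um = np.full((spec.nx, spec.ny), float(base))
    return (depth_um / spec.axial_pitch_um).astype(np.float64)


def _complex_gaussian(rng: np.random.Generator, shape, scale: float = 1.0):
    """Circular complex Gaussian with E|g|^2 = scale^2 (per-component
    variance scale^2/2)."""
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    g = (re + 1j * im).astype(np.complex64)
    g *= np.float32(scale / math.sqrt(2.0))
    return g


def _axial_shift(frame: np.ndarray, shift: int) -> np.ndarray:
    """Shift a (z, x) frame along z by ``shift`` voxels, zero-filling."""
    if shift == 0:
        return frame
    out = np.zeros_like(frame)
    if shift > 0:
        out[shift:] = frame[:-shift]
    else:
        out[:shift] = frame[-shift:]
    return out


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> Tuple[RepeatedBScanVolume, PhantomGroundTruth]:
    """Generate a repeated-B-scan volume and its ground truth.

    The speckle field is drawn once for the static tissue and re-drawn per
    repeat inside blood vessels (mixed with the static field according to
    ``blood_decorrelation``); additive complex noise (per-component std
    ``noise_sigma``) and global axial bulk shifts are applied per repeat.
    Identical ``(spec, seed)`` pairs produce bit-identical output.
    """
    rng = np.random.default_rng(int(seed) % 2**63)
    nz, nx, ny = spec.grid_shape
    R = spec.n_repeats

    surface = _surface_map(spec)  # (nx, ny), fractional voxels
    edj = surface + spec.epidermis_thickness_um / spec.axial_pitch_um

    lymph = _rasterize_tubes(spec, spec.lymph_tubes)
    blood = _rasterize_tubes(spec, spec.blood_tubes)
    if (lymph & blood).any():
        raise ValueError(
            "lymph and blood tubes overlap; phantom masks must be disjoint"
        )

    z_idx = np.arange(nz, dtype=np.float32)[:, None, None]
    depth_vox = z_idx - surface[None, :, :].astype(np.float32)  # below surface

    amp = np.zeros((nz, nx, ny), dtype=np.float32)
    tissue = depth_vox >= 0
    amp[tissue] = spec.dermis_amplitude
    epi_vox = spec.epidermis_thickness_um / spec.axial_pitch_um
    epidermis = tissue & (depth_vox < epi_vox)
    amp[epidermis] *= spec.epidermis_multiplier
    amp[lymph] *= spec.lymph_amplitude_scale
    # round-trip attenuation on intensity: amplitude decays as exp(-mu z)
    depth_mm = np.clip(depth_vox, 0, None) * (spec.axial_pitch_um / 1000.0)
    amp *= np.exp(-spec.attenuation_per_mm * depth_mm, dtype=np.float32)

    g_static = _complex_gaussian(rng, (nz, nx, ny))
    static_field = (amp * g_static).astype(np.complex64)

    shifts = np.asarray(
        spec.bulk_shifts if spec.bulk_shifts is not None else [0] * R,
        dtype=np.int64,
    )
    f = spec.blood_decorrelation
    keep = np.float32(math.sqrt(1.0 - f))
    fresh = np.float32(math.sqrt(f))
    n_blood = int(blood.sum())
    blood_amp = amp[blood]
    blood_static = static_field[blood]

    data = np.empty((ny, R, nz, nx), dtype=np.complex64)
    for r in range(R):
        field = static_field
        if n_blood:
            field = static_field.copy()
            g_new = _complex_gaussian(rng, (n_blood,))
            field[blood] = keep * blood_static + fresh * (blood_amp * g_new)
        if spec.noise_sigma > 0:
            noise = rng.standard_normal((nz, nx, ny), dtype=np.float32) + 1j * (
                rng.standard_normal((nz, nx, ny), dtype=np.float32)
            )
            field = field + np.float32(spec.noise_sigma) * noise.astype(
                np.complex64
            )
        s = int(shifts[r])
        frame_zxy = field
        if s != 0:
            shifted = np.zeros_like(field)
            if s > 0:
                shifted[s:] = field[:-s]
            else:
                shifted[:s] = field[-s:]
            frame_zxy = shifted
        # (z, x, y) -> per-location B-frames (y, z, x)
        data[:, r] = np.moveaxis(frame_zxy, 2, 0)

    volume = RepeatedBScanVolume(
        data=data, protocol=spec.protocol(), source="phantom"
    )
    truth = PhantomGroundTruth(
        lymph_mask=lymph,
        blood_mask=blood,
        surface_map=surface,
        edj_map=edj,
        bulk_shifts=shifts,
    )
    return volume, truth


def analytic_tube_volume_fraction(
    spec: PhantomSpec, which: str = "lymph"
) -> float:
    """Analytic tube volume (sum of pi r^2 L cylinders) over grid volume."""
    tubes = spec.lymph_tubes if which == "lymph" else spec.blood_tubes
    vol_um3 = sum(
        math.pi
        * t.radius_um**2
        * t.length_um(spec.axial_pitch_um, spec.lateral_pitch_um)
        for t in tubes
    )
    grid_um3 = (
        spec.nz * spec.axial_pitch_um * (spec.nx * spec.lateral_pitch_um)
        * (spec.ny * spec.lateral_pitch_um)
    )
    return vol_um3 / grid_um3


def analytic_projected_area_fraction(
    spec: PhantomSpec, which: str = "lymph", tubes: Sequence[Tube] = None
) -> float:
    """Analytic en-face footprint (2 r L rectangles) over field area.

    Valid for the default layout where tube lanes do not overlap laterally.
    """
    if tubes is None:
        tubes = spec.lymph_tubes if which == "lymph" else spec.blood_tubes
    area_um2 = 0.0
    for t in tubes:
        pts = np.asarray(t.points, dtype=float)
        lat = pts[:, 1:] * spec.lateral_pitch_um  # (x, y) um
        length = float(np.linalg.norm(np.diff(lat, axis=0), axis=1).sum())
        area_um2 += 2.0 * t.radius_um * length
    field_um2 = (spec.nx * spec.lateral_pitch_um) * (
        spec.ny * spec.lateral_pitch_um
    )
    return area_um2 / field_um2


def project_mask_to_slab(
    mask: np.ndarray,
    edj_map: np.ndarray,
    slab_um: Tuple[float, float],
    axial_pitch_um: float,
) -> np.ndarray:
    """En-face projection of a (z, x, y) mask restricted to a dermal slab.

    The slab is the half-open depth band ``[d1, d2)`` micrometres below the
    local EDJ.  Returns an (x, y) boolean image: True where any mask voxel
    falls inside the band.
    """
    d1, d2 = slab_um
    nz = mask.shape[0]
    z = np.arange(nz, dtype=np.float64)[:, None, None]
    depth_um = (z - edj_map[None, :, :]) * axial_pitch_um
    in_slab = (depth_um >= d1) & (depth_um < d2)
    return (mask & in_slab).any(axis=0)
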