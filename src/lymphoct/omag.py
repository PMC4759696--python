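"""Optical microangiography (OMAG): blood-flow contrast from repeated B-frames.

Moving red blood cells decorrelate the OCT speckle between B-frames
repeated at the same location, while static tissue (including lymph
lumens) returns a nearly constant signal.  Averaging the magnitude of the
complex signal difference between adjacent repeats therefore yields a
flow-intensity image:

    flow(z, x) = 1/(R-1) * sum_{i=1}^{R-1} | C_{i+1}(z, x) - C_i(z, x) |

Axial bulk motion between repeats is removed first by a global,
integer-voxel, cross-correlation registration against the first repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volume_io import RepeatedBScanVolume, ScanProtocol

__all__ = [
    "AngiogramVolume",
    "DepthEncodedMip",
    "register_repeats",
    "compute_flow",
    "flow_volume",
    "gaussian_kernel2d",
    "smooth",
    "mip_enface",
    "depth_encoded_mip",
    "render_depth_encoded",
]


@dataclass
class AngiogramVolume:
    """Blood-flow intensity volume, ordered (z, x, y), nonnegative."""

    data: np.ndarray
    kernel_size: Optional[int] = None
    protocol: Optional[ScanProtocol] = None
    #: number of axial voxels at each end possibly invalidated by
    #: registration zero-fill (max |shift| observed)
    valid_margin: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("angiogram must be 3D (z, x, y)")
        if not np.isfinite(self.data).all():
            raise ValueError("angiogram contains non-finite values")
        if (self.data < 0).any():
            raise ValueError("flow intensity must be nonnegative")


@dataclass
class DepthEncodedMip:
    """Depth-resolved maximum projection: the en-face maximum and the depth
    at which it occurs (shallowest on ties), for depth-color-coded display."""

    value: np.ndarray
    depth: np.ndarray
    colormap: str = "turbo"
    degenerate: bool = False


def _axial_shift(frame: np.ndarray, shift: int) -> np.ndarray:
    if shift == 0:
        return frame.copy()
    out = np.zeros_like(frame)
    if shift > 0:
        out[shift:] = frame[:-shift]
    else:
        out[:shift] = frame[-shift:]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return -np.inf
    return float((a @ b) / denom)


def register_repeats(
    frames: Sequence[np.ndarray] | np.ndarray,
    max_shift: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Align repeated B-frames axially to the first frame.

    For each frame the integer axial displacement within ``+-max_shift``
    (default nz//4) that maximizes the normalized cross-correlation of the
    amplitude over the overlapping rows is detected; the frame is shifted
    back by that amount.  Vacated rows are zero-filled; callers should
    exclude a ``max(|shift|)`` margin from statistics near the axial ends.

    Returns ``(aligned, shifts)`` where ``shifts[i]`` is the detected
    displacement of frame ``i`` relative to frame 0 (``shifts[0] == 0``);
    ties prefer the smallest magnitude.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need >= 2 frames of equal shape (R, z, x)")
    R, nz, _ = frames.shape
    if max_shift is None:
        max_shift = nz // 4
    max_shift = int(min(max_shift, nz - 2))

    amp = np.abs(frames).astype(np.float32)
    ref = amp[0]
    if not ref.any():
        warnings.warn("reference frame is all zero; assuming zero shifts")
        return frames.copy(), np.zeros(R, dtype=np.int64)

    # search order 0, -1, +1, -2, +2, ... so ties resolve to smallest |s|
    search = [0]
    for s in range(1, max_shift + 1):
        search.extend([-s, s])

    shifts = np.zeros(R, dtype=np.int64)
    aligned = np.empty_like(frames)
    aligned[0] = frames[0]
    for i in range(1, R):
        fr = amp[i]
        if not fr.any():
            warnings.warn(f"frame {i} is all zero; assuming zero shift")
            aligned[i] = frames[i]
            continue
        best_s, best_c = 0, -np.inf
        for s in search:
            # displacement s: frame content sits s rows deeper than ref
            if s >= 0:
                c = _ncc(ref[: nz - s], fr[s:] if s else fr)
            else:
                c = _ncc(ref[-s:], fr[:s])
            if c > best_c:
                best_c, best_s = c, s
        shifts[i] = best_s
        aligned[i] = _axial_shift(frames[i], -best_s)
    return aligned, shifts


def compute_flow(aligned: np.ndarray, mode: str = "complex") -> np.ndarray:
    """Mean magnitude of adjacent-repeat signal differences.

    ``mode='complex'`` differences the full complex signal; ``'amplitude'``
    differences amplitudes (for amplitude-only acquisitions).  The result
    is invariant to a global phase rotation of all repeats in complex mode.
    """
    aligned = np.asarray(aligned)
    if aligned.ndim < 1 or aligned.shape[0] < 2:
        raise ValueError("flow needs at least 2 repeated frames")
    if mode not in ("complex", "amplitude"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "amplitude":
        aligned = np.abs(aligned)
    elif not np.iscomplexobj(aligned):
        # amplitude data passed in complex mode: fall back to amplitude
        aligned = np.abs(aligned)
    diffs = np.abs(np.diff(aligned, axis=0)).astype(np.float32)
    return diffs.mean(axis=0)


def flow_volume(
    volume: RepeatedBScanVolume,
    mode: str = "complex",
    register: bool = True,
    max_shift: Optional[int] = None,
) -> AngiogramVolume:
    """OMAG flow volume from a repeated-B-scan record.

    Runs per-location registration (optional) and adjacent differencing,
    assembling a (z, x, y) flow-intensity volume.
    """
    if not volume.is_complex and mode == "complex":
        mode = "amplitude"
    ny, R, nz, nx = volume.shape
    if R < 2:
        raise ValueError("OMAG needs >= 2 repeats per location")
    out = np.empty((nz, nx, ny), dtype=np.float32)
    margin = 0
    for iy in range(ny):
        frames = volume.data[iy]
        if register:
            frames, shifts = register_repeats(frames, max_shift=max_shift)
            margin = max(margin, int(np.abs(shifts).max()))
        out[:, :, iy] = compute_flow(frames, mode=mode)
    return AngiogramVolume(
        data=out, protocol=volume.protocol, valid_margin=margin
    )


def gaussian_kernel2d(size: int = 3, sigma: float = 0.8) -> np.ndarray:
    """Odd-sized 2D Gaussian kernel normalized to unit sum."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {size}")
    r = size // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth(
    angiogram: AngiogramVolume | np.ndarray,
    size: int = 3,
    sigma: float = 0.8,
) -> AngiogramVolume | np.ndarray:
    """Gaussian noise-reduction filter applied per en-face (x, y) plane.

    Borders are handled by reflection, so a constant volume is unchanged
    and the total sum is preserved up to floating-point error.
    """
    kernel = gaussian_kernel2d(size, sigma)
    if isinstance(angiogram, AngiogramVolume):
        data = ndimage.convolve(
            angiogram.data, kernel[None, :, :], mode="reflect"
        )
        return AngiogramVolume(
            data=data,
            kernel_size=size,
            protocol=angiogram.protocol,
            valid_margin=angiogram.valid_margin,
        )
    arr = np.asarray(angiogram, dtype=np.float32)
    if arr.ndim == 2:
        return ndimage.convolve(arr, kernel, mode="reflect")
    if arr.ndim == 3:
        return ndimage.convolve(arr, kernel[None, :, :], mode="reflect")
    raise ValueError("expected a 2D image or 3D (z, x, y) volume")


def _zslice(data: np.ndarray, z_range: Optional[Tuple[int, int]]):
    nz = data.shape[0]
    if z_range is None:
        return data
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(
            f"empty or out-of-range depth range [{z0}, {z1}) for nz={nz}"
        )
    return data[z0:z1]


def mip_enface(
    angiogram: AngiogramVolume | np.ndarray,
    z_range: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Maximum intensity projection onto the en-face plane.

    Maps the maximal value along each A-line (optionally restricted to the
    half-open depth range ``[z0, z1)``) to an (x, y) image.
    """
    data = angiogram.data if isinstance(angiogram, AngiogramVolume) else angiogram
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("expected a 3D (z, x, y) volume")
    return _zslice(data, z_range).max(axis=0)


def depth_encoded_mip(
    angiogram: AngiogramVolume | np.ndarray,
    z_range: Optional[Tuple[int, int]] = None,
    colormap: str = "turbo",
) -> DepthEncodedMip:
    """Maximum projection with the depth of the maximum, for depth coding.

    Ties resolve to the shallowest depth (first hit).  An all-zero volume
    yields depth 0 everywhere and is flagged ``degenerate``.
    """
    data = angiogram.data if isinstance(angiogram, AngiogramVolume) else angiogram
    data = np.asarray(data)
    if data.ndim != 3 or data.size == 0:
        raise ValueError("expected a nonempty 3D (z, x, y) volume")
    sub = _zslice(data, z_range)
    z0 = 0 if z_range is None else z_range[0]
    value = sub.max(axis=0)
    depth = sub.argmax(axis=0).astype(np.int64) + z0
    return DepthEncodedMip(
        value=value,
        depth=depth,
        colormap=colormap,
        degenerate=not bool(data.any()),
    )


def render_depth_encoded(
    mip: DepthEncodedMip, axial_pitch_um: Optional[float] = None
) -> np.ndarray:
    """RGB uint8 rendering: hue encodes depth, brightness encodes flow."""
    import matplotlib.cm as cm

    depth = mip.depth.astype(np.float64)
    span = depth.max() - depth.min()
    norm_depth = (depth - depth.min()) / span if span > 0 else np.zeros_like(depth)
    vmax = mip.value.max()
    norm_val = mip.value / vmax if vmax > 0 else np.zeros_like(mip.value)
    rgba = cm.get_cmap(mip.colormap)(norm_depth)
    rgb = rgba[..., :3] * norm_val[..., None]
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
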