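"""OCT lymphangiography (OLAG): mapping lymphatic vessels as dark lumens.

Lymph fluid is nearly transparent at OCT wavelengths, so lymphatic lumens
appear as low-scattering (dark) regions in the structural image.  In
highly scattering skin their contrast is destroyed by depth-dependent
attenuation, so the chain is:

1. attenuation compensation — each A-line is renormalized by (twice) the
   remaining tail energy, ``A(z) = I(z)^n / (2 * sum_{u >= z} I(u)^n)``,
   which flattens the depth decay, bounds the output in [0, 0.5] and makes
   the epidermis visibly brighter than the dermis;
2. layer segmentation — tissue surface by threshold crossing, then the
   epidermal--dermal junction (EDJ) as the steepest intensity drop below
   the surface;
3. flattening to the EDJ so that en-face slices follow the dermal layers;
4. per-slice histogram (rank) equalization of the en-face slices;
5. sorted minimum intensity projection (sMIP) over dermal depth slabs —
   the per-pixel average of the k smallest intensities in the slab, which
   emphasizes consistently dark lumens over single-voxel dropouts;
6. thresholding and morphological cleanup into a lymphatic-vessel mask;
7. optional mosaicking of adjacent fields into a wide-field map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from .volume_io import RepeatedBScanVolume

__all__ = [
    "SurfaceMaps",
    "LymphEnfaceMap",
    "LymphMask",
    "OlagParams",
    "SlabResult",
    "OlagResult",
    "compensate_attenuation",
    "detect_surface",
    "segment_edj",
    "flatten",
    "unflatten",
    "enface_equalize",
    "sorted_min_projection",
    "smip",
    "extract_lymph_mask",
    "mosaic",
    "lymphangiography",
]

DEFAULT_SLABS_UM: Tuple[Tuple[float, float], ...] = (
    (0.0, 200.0),
    (200.0, 400.0),
    (400.0, 600.0),
)


@dataclass
class SurfaceMaps:
    """Per-(x, y) tissue-surface and EDJ depths, in (fractional) voxels.

    ``flags`` marks columns where detection failed and the value was
    filled from neighbors; flagged columns are excluded from downstream
    statistics.
    """

    surface: np.ndarray
    edj: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        if not (self.surface.shape == self.edj.shape == self.flags.shape):
            raise ValueError("surface, EDJ and flag maps must share a shape")
        ok = ~self.flags
        if ok.any() and (self.edj[ok] < self.surface[ok] - 1e-9).any():
            raise ValueError("EDJ must lie at or below the surface")


@dataclass
class LymphEnfaceMap:
    """sMIP image for one dermal slab.

    ``slab_um`` is the half-open depth band below the EDJ; ``k`` the number
    of sorted values averaged; ``invalid`` marks pixels whose slab column
    held fewer than ``k`` valid voxels.
    """

    image: np.ndarray
    slab_um: Tuple[float, float]
    k: int
    invalid: np.ndarray


@dataclass
class LymphMask:
    """Binary lymphatic-vessel mask with the parameters that produced it."""

    mask: np.ndarray
    threshold: Optional[float]
    min_size: int
    elongation_ratio: Optional[float] = None


@dataclass
class OlagParams:
    """Tunable parameters of the lymphangiography chain."""

    exponent: float = 2.0
    window_um: Tuple[float, float] = (40.0, 300.0)
    slabs_um: Tuple[Tuple[float, float], ...] = DEFAULT_SLABS_UM
    #: fraction of the slab thickness averaged by the sMIP (min 1 voxel)
    k_frac: float = 0.25
    #: "pre" = equalize en-face slices then project (default);
    #: "post" = project raw intensities then equalize the map; "none"
    equalize: str = "pre"
    threshold: str = "otsu"
    percentile: float = 30.0
    min_size: int = 10
    elongation_ratio: Optional[float] = None
    mask_smooth_size: int = 3
    mask_smooth_sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.equalize not in ("pre", "post", "none"):
            raise ValueError("equalize must be 'pre', 'post' or 'none'")
        if not (0.0 < self.k_frac <= 1.0):
            raise ValueError("k_frac must be in (0, 1]")
        for d1, d2 in self.slabs_um:
            if d1 < 0 or d2 <= d1:
                raise ValueError(f"invalid slab [{d1}, {d2})")


@dataclass
class SlabResult:
    slab_um: Tuple[float, float]
    enface: LymphEnfaceMap
    mask: LymphMask


@dataclass
class OlagResult:
    surfaces: SurfaceMaps
    slabs: List[SlabResult]
    flatten_index: int
    params: OlagParams


# ---------------------------------------------------------------------------
# attenuation compensation
# ---------------------------------------------------------------------------

def compensate_attenuation(
    intensity: np.ndarray, exponent: float = 2.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-A-line attenuation compensation.

    ``A(z) = I(z)^n / (2 * sum_{u >= z} I(u)^n)`` with the tail sum
    inclusive of ``z``, so the output is bounded in [0, 0.5] and the
    deepest nonzero voxel maps to exactly 0.5.  Raising the intensity to
    ``n > 1`` additionally sharpens contrast.

    Returns ``(compensated, flags)`` where ``flags`` marks all-zero
    A-lines (returned as zeros, no division by zero).
    """
    I = np.asarray(intensity, dtype=np.float64)
    if (I < 0).any():
        raise ValueError("intensities must be nonnegative")
    p = I**exponent
    # inclusive tail sum: flip, cumsum, flip back
    tail = np.flip(np.cumsum(np.flip(p, axis=0), axis=0), axis=0)
    flags = tail[0] == 0  # all-zero A-lines (lateral shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        comp = p / (2.0 * tail)
    comp = np.nan_to_num(comp, nan=0.0, posinf=0.0, neginf=0.0)
    return comp.astype(np.float32), np.asarray(flags)


# ---------------------------------------------------------------------------
# layer segmentation
# ---------------------------------------------------------------------------

def _fill_from_neighbors(values: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Replace flagged entries by the nearest unflagged value."""
    if not flags.any():
        return values
    if flags.all():
        return np.zeros_like(values)
    idx = ndimage.distance_transform_edt(
        flags, return_distances=False, return_indices=True
    )
    return values[tuple(idx)]


def detect_surface(
    amplitude: np.ndarray,
    k_mad: float = 8.0,
    noise_rows: Optional[int] = None,
    min_run: int = 3,
    median_size: int = 5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Detect the tissue surface per (x, y) column.

    The axially smoothed amplitude is compared against a noise threshold
    (median + ``k_mad`` scaled MADs, estimated from the shallowest rows,
    which are assumed to lie above the tissue); the surface is the first
    depth where the signal stays above threshold for ``min_run`` voxels.
    Columns that never cross are flagged and filled from neighbors; the
    map is median-smoothed laterally.
    """
    amp = np.asarray(amplitude, dtype=np.float32)
    if amp.ndim != 3:
        raise ValueError("expected a (z, x, y) amplitude volume")
    nz = amp.shape[0]
    if noise_rows is None:
        noise_rows = max(2, nz // 16)
    sm = ndimage.uniform_filter1d(amp, size=3, axis=0)

    noise = sm[:noise_rows].ravel()
    med = float(np.median(noise))
    mad = float(np.median(np.abs(noise - med)))
    thr = med + k_mad * 1.4826 * mad
    if thr <= 0:
        thr = np.finfo(np.float32).tiny

    above = sm > thr
    run = above[: nz - min_run + 1].copy()
    for i in range(1, min_run):
        run &= above[i : nz - min_run + 1 + i]
    found = run.any(axis=0)
    surface = run.argmax(axis=0).astype(np.float64)
    flags = ~found
    if flags.all():
        return np.zeros(flags.shape), flags
    surface = _fill_from_neighbors(surface, flags)
    surface = ndimage.median_filter(surface, size=median_size, mode="nearest")
    return surface, flags


def segment_edj(
    compensated: np.ndarray,
    surface: np.ndarray,
    axial_pitch_um: float,
    window_um: Tuple[float, float] = (40.0, 300.0),
    contrast_min: float = 1.15,
    lateral_size: int = 5,
    axial_sigma: float = 1.5,
    median_size: int = 5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Locate the epidermal--dermal junction per column.

    Within ``[surface + w0, surface + w1]`` (micrometres) the EDJ is the
    depth of the steepest negative axial gradient of the laterally and
    axially smoothed compensated intensity.  Columns whose epidermis-to-
    dermis intensity ratio falls below ``contrast_min`` (no detectable
    junction) are flagged and filled from neighbors.
    """
    comp = np.asarray(compensated, dtype=np.float32)
    if comp.ndim != 3:
        raise ValueError("expected a (z, x, y) compensated volume")
    nz = comp.shape[0]
    w0 = window_um[0] / axial_pitch_um
    w1 = window_um[1] / axial_pitch_um
    if w1 <= w0:
        raise ValueError("search window must have positive extent")
    med_surf = float(np.median(surface))
    if med_surf + w0 >= nz - 1:
        raise ValueError(
            f"EDJ search window [{window_um[0]}, {window_um[1]}] um below "
            f"the surface exceeds the volume depth ({nz} voxels)"
        )

    sm = ndimage.uniform_filter(comp, size=(1, lateral_size, lateral_size))
    sm = ndimage.gaussian_filter1d(sm, sigma=axial_sigma, axis=0)
    grad = np.gradient(sm, axis=0)

    z = np.arange(nz, dtype=np.float64)[:, None, None]
    lo = surface[None, :, :] + w0
    hi = np.minimum(surface[None, :, :] + w1, nz - 1)
    in_window = (z >= lo) & (z <= hi)
    masked = np.where(in_window, grad, np.inf)
    edj = masked.argmin(axis=0).astype(np.float64)
    no_window = ~in_window.any(axis=0)

    # contrast check: mean compensated intensity above vs below candidate
    csum = np.cumsum(sm, axis=0)
    surf_i = np.clip(np.round(surface).astype(np.int64), 0, nz - 1)
    edj_i = np.clip(edj.astype(np.int64), 0, nz - 1)

    def band_mean(a_idx, b_idx):
        a_idx = np.clip(a_idx, 0, nz - 1)
        b_idx = np.clip(b_idx, 0, nz - 1)
        width = np.maximum(b_idx - a_idx, 1)
        top = np.take_along_axis(csum, a_idx[None], axis=0)[0]
        bot = np.take_along_axis(csum, b_idx[None], axis=0)[0]
        return (bot - top) / width

    epi = band_mean(surf_i, edj_i)
    below = band_mean(edj_i, edj_i + int(round(100.0 / axial_pitch_um)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = epi / below
    low_contrast = ~np.isfinite(ratio) | (ratio < contrast_min)
    flags = no_window | low_contrast

    if flags.all():
        edj = np.maximum(surface, 0.0)
        return edj, flags
    edj = _fill_from_neighbors(edj, flags)
    edj = ndimage.median_filter(edj, size=median_size, mode="nearest")
    edj = np.maximum(edj, surface)
    return edj, flags


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------

def flatten(
    volume: np.ndarray,
    reference: np.ndarray,
    target: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Shift each A-line so the reference depth sits at a constant index.

    Returns ``(flattened, valid, target)``: the flattened float volume with
    ``NaN`` in vacated voxels, the boolean validity mask, and the index at
    which the reference now lies (default: the rounded-up maximum of the
    reference map, so every column shifts downward or not at all).
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a (z, x, y) volume")
    nz = vol.shape[0]
    ref = np.asarray(reference, dtype=np.float64)
    if (ref < 0).any() or (ref >= nz).any():
        raise ValueError("reference map out of depth range")
    if target is None:
        target = int(math.ceil(np.nanmax(ref)))
    shift = target - np.round(ref).astype(np.int64)  # (x, y)

    z_out = np.arange(nz, dtype=np.int64)[:, None, None]
    z_src = z_out - shift[None, :, :]
    valid = (z_src >= 0) & (z_src < nz)
    z_clip = np.clip(z_src, 0, nz - 1)
    flat = np.take_along_axis(vol, z_clip, axis=0).astype(np.float64)
    flat[~valid] = np.nan
    return flat.astype(np.float32), valid, target


def unflatten(
    flattened: np.ndarray, reference: np.ndarray, target: int
) -> np.ndarray:
    """Inverse of :func:`flatten` on the valid region (NaN elsewhere)."""
    flat = np.asarray(flattened)
    nz = flat.shape[0]
    shift = target - np.round(np.asarray(reference, dtype=np.float64)).astype(
        np.int64
    )
    z_out = np.arange(nz, dtype=np.int64)[:, None, None]
    z_src = z_out + shift[None, :, :]
    valid = (z_src >= 0) & (z_src < nz)
    z_clip = np.clip(z_src, 0, nz - 1)
    out = np.take_along_axis(flat, z_clip, axis=0).astype(np.float64)
    out[~valid] = np.nan
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# en-face contrast and projection
# ---------------------------------------------------------------------------

def enface_equalize(
    image: np.ndarray, valid: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, bool]:
    """Global histogram equalization of an en-face slice by rank transform.

    Valid pixels are mapped to ``(rank - 0.5) / N`` so the output empirical
    distribution is uniform on [0, 1] and rank order is preserved exactly.
    Invalid pixels stay NaN.  A constant slice cannot be equalized; it is
    returned as 0.5 with the flag set.
    """
    img = np.asarray(image, dtype=np.float64)
    if valid is None:
        valid = np.isfinite(img)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(img)
    out = np.full(img.shape, np.nan)
    vals = img[valid]
    if vals.size == 0:
        return out.astype(np.float32), True
    if np.ptp(vals) == 0:
        out[valid] = 0.5
        return out.astype(np.float32), True
    ranks = stats.rankdata(vals, method="average")
    out[valid] = (ranks - 0.5) / vals.size
    return out.astype(np.float32), False


def sorted_min_projection(
    stack: np.ndarray, k: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Average of the k smallest valid values along axis 0.

    ``stack`` is (depth, x, y) with NaN marking invalid voxels.  Pixels
    with fewer than ``k`` valid voxels are flagged; if they have at least
    one valid voxel the mean of what is available is returned, otherwise
    NaN.  ``k=1`` reduces to the minimum projection, ``k=depth`` (on fully
    valid columns) to the mean projection.
    """
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3:
        raise ValueError("expected a (depth, x, y) stack")
    d = stack.shape[0]
    if not (1 <= k <= d):
        raise ValueError(f"k={k} out of range [1, {d}] for slab thickness {d}")
    counts = np.isfinite(stack).sum(axis=0)
    srt = np.sort(stack, axis=0)  # NaNs sort to the end
    topk = srt[:k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        image = np.nanmean(topk, axis=0)
    flagged = counts < k
    return image.astype(np.float32), flagged


def smip(
    flattened: np.ndarray,
    flatten_index: int,
    slab_um: Tuple[float, float],
    axial_pitch_um: float,
    k: Optional[int] = None,
    k_frac: float = 0.25,
    equalize: str = "pre",
) -> LymphEnfaceMap:
    """Sorted minimum intensity projection over a dermal slab.

    The slab ``[d1, d2)`` micrometres below the EDJ is taken from a volume
    flattened so the EDJ sits at ``flatten_index``.  With
    ``equalize='pre'`` each en-face slice is rank-equalized before the
    projection; ``'post'`` equalizes the projected map; ``'none'`` projects
    raw intensities.
    """
    d1, d2 = slab_um
    if d1 < 0 or d2 <= d1:
        raise ValueError(f"invalid slab [{d1}, {d2})")
    nz = flattened.shape[0]
    z0 = flatten_index + int(round(d1 / axial_pitch_um))
    z1 = flatten_index + int(round(d2 / axial_pitch_um))
    z1 = min(z1, nz)
    if z0 >= z1:
        raise ValueError(
            f"slab [{d1}, {d2}) um lies outside the flattened volume"
        )
    stack = np.array(flattened[z0:z1], dtype=np.float32)
    if equalize == "pre":
        for i in range(stack.shape[0]):
            stack[i], _ = enface_equalize(stack[i])
    if k is None:
        k = max(1, int(round(k_frac * stack.shape[0])))
    image, flagged = sorted_min_projection(stack, k)
    if equalize == "post":
        eq, _ = enface_equalize(image, valid=~flagged)
        image = np.where(flagged, image, eq)
    return LymphEnfaceMap(image=image, slab_um=(d1, d2), k=k, invalid=flagged)


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def extract_lymph_mask(
    enface: LymphEnfaceMap | np.ndarray,
    valid: Optional[np.ndarray] = None,
    method: str = "otsu",
    percentile: float = 30.0,
    min_size: int = 10,
    elongation_ratio: Optional[float] = None,
    smooth_size: int = 3,
    smooth_sigma: float = 0.8,
) -> LymphMask:
    """Binarize an sMIP map into a lymphatic-vessel mask.

    The map is first smoothed with a small Gaussian (``smooth_size=0``
    disables it): single-pixel projection noise otherwise dominates the
    histogram and global thresholds collapse onto the background mode.
    Pixels darker than the threshold (Otsu by default, or a fixed
    percentile) are candidates; connected components smaller than
    ``min_size`` pixels are removed, and optionally components whose
    skeleton length over equivalent diameter falls below
    ``elongation_ratio`` (blob-like, e.g. edema) are dropped, keeping
    elongated vessel-like structures.
    """
    if isinstance(enface, LymphEnfaceMap):
        image = enface.image
        base_valid = ~enface.invalid
    else:
        image = np.asarray(enface)
        base_valid = np.ones(image.shape, dtype=bool)
    if valid is not None:
        base_valid = base_valid & np.asarray(valid, dtype=bool)
    base_valid = base_valid & np.isfinite(image)

    if smooth_size and smooth_size > 1 and base_valid.any():
        from .omag import gaussian_kernel2d

        filled = np.where(base_valid, image, np.median(image[base_valid]))
        image = ndimage.convolve(
            filled.astype(np.float64),
            gaussian_kernel2d(smooth_size, smooth_sigma),
            mode="reflect",
        )

    vals = image[base_valid]
    if vals.size == 0 or np.ptp(vals) == 0:
        warnings.warn("constant or empty map: returning an empty lymph mask")
        return LymphMask(
            mask=np.zeros(image.shape, dtype=bool),
            threshold=None,
            min_size=min_size,
            elongation_ratio=elongation_ratio,
        )
    if method == "otsu":
        thr = float(threshold_otsu(vals))
    elif method == "percentile":
        thr = float(np.percentile(vals, percentile))
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    mask = base_valid & (image < thr)
    if min_size > 1 and mask.any():
        labels = cc_label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = (counts >= min_size)[labels]
    if elongation_ratio is not None and mask.any():
        labels = cc_label(mask, connectivity=2)
        keep = np.zeros(labels.max() + 1, dtype=bool)
        for region in regionprops(labels):
            component = labels[region.slice] == region.label
            skel_len = int(skeletonize(component).sum())
            eq_diam = region.equivalent_diameter_area
            keep[region.label] = (
                eq_diam > 0 and skel_len / eq_diam >= elongation_ratio
            )
        mask = keep[labels]
    if not mask.any():
        warnings.warn("lymph mask is empty after filtering")
    return LymphMask(
        mask=mask,
        threshold=thr,
        min_size=min_size,
        elongation_ratio=elongation_ratio,
    )


# ---------------------------------------------------------------------------
# mosaicking
# ---------------------------------------------------------------------------

def _refine_shift(
    fixed: np.ndarray, moving: np.ndarray, search: int
) -> Tuple[int, int]:
    """Integer (dy, dx) maximizing NCC of two equally shaped strips."""
    if search <= 0:
        return 0, 0
    f = fixed.astype(np.float64)
    m = moving.astype(np.float64)
    if np.ptp(f) == 0 or np.ptp(m) == 0:
        return 0, 0
    best = (0, 0)
    best_c = -np.inf
    h, w = f.shape
    for dy in range(-search, search + 1):
        for dx in range(-search, search + 1):
            y0f, y1f = max(0, dy), min(h, h + dy)
            x0f, x1f = max(0, dx), min(w, w + dx)
            if y1f - y0f < 2 or x1f - x0f < 2:
                continue
            a = f[y0f:y1f, x0f:x1f]
            b = m[y0f - dy : y1f - dy, x0f - dx : x1f - dx]
            av = a - a.mean()
            bv = b - b.mean()
            den = math.sqrt((av * av).sum() * (bv * bv).sum())
            if den == 0:
                continue
            c = (av * bv).sum() / den
            if c > best_c + 1e-12:
                best_c = c
                best = (dy, dx)
    return best


def mosaic(
    tiles: Sequence[Sequence[np.ndarray]],
    overlap_mm: float,
    pixel_pitch_um: float,
    refine: bool = True,
    search: Optional[int] = None,
) -> np.ndarray:
    """Stitch a rectangular grid of en-face tiles into one canvas.

    Tiles are placed at nominal positions spaced by (tile - overlap); each
    tile's position is refined by cross-correlation against its top/left
    neighbors within the overlap, then blended with linear feathering in
    the overlap bands.  A 3x3 grid of 3 mm tiles with 0.5 mm seams spans
    8 mm x 8 mm.
    """
    rows = len(tiles)
    if rows == 0 or len(tiles[0]) == 0:
        raise ValueError("empty tile grid")
    cols = len(tiles[0])
    if any(len(r) != cols for r in tiles):
        raise ValueError("tile grid must be rectangular")
    shape = np.asarray(tiles[0][0]).shape
    for r in tiles:
        for t in r:
            if np.asarray(t).shape != shape:
                raise ValueError("all tiles must have equal shape")
    h, w = shape
    ov = int(round(overlap_mm * 1000.0 / pixel_pitch_um))
    if ov < 0 or ov >= min(h, w):
        raise ValueError(
            f"overlap ({ov} px) must be nonnegative and smaller than the tile"
        )
    if search is None:
        search = min(max(ov // 3, 0), 8)

    H = rows * h - (rows - 1) * ov
    W = cols * w - (cols - 1) * ov
    num = np.zeros((H, W), dtype=np.float64)
    den = np.zeros((H, W), dtype=np.float64)

    ramp = (np.arange(ov, dtype=np.float64) + 1.0) / (ov + 1.0) if ov else None

    for i in range(rows):
        for j in range(cols):
            tile = np.asarray(tiles[i][j], dtype=np.float64)
            oy = i * (h - ov)
            ox = j * (w - ov)
            if refine and ov > 0:
                dys, dxs = [], []
                if i > 0:
                    top = np.asarray(tiles[i - 1][j], dtype=np.float64)
                    dy, dx = _refine_shift(top[h - ov :], tile[:ov], search)
                    dys.append(dy)
                    dxs.append(dx)
                if j > 0:
                    left = np.asarray(tiles[i][j - 1], dtype=np.float64)
                    dy, dx = _refine_shift(left[:, w - ov :], tile[:, :ov], search)
                    dys.append(dy)
                    dxs.append(dx)
                if dys:
                    oy += int(round(np.mean(dys)))
                    ox += int(round(np.mean(dxs)))
                oy = int(np.clip(oy, 0, H - h))
                ox = int(np.clip(ox, 0, W - w))

            wy = np.ones(h)
            wx = np.ones(w)
            if ov:
                if i > 0:
                    wy[:ov] = ramp
                if i < rows - 1:
                    wy[h - ov :] = ramp[::-1]
                if j > 0:
                    wx[:ov] = ramp
                if j < cols - 1:
                    wx[w - ov :] = ramp[::-1]
            weight = np.outer(wy, wx)
            num[oy : oy + h, ox : ox + w] += weight * tile
            den[oy : oy + h, ox : ox + w] += weight

    out = np.zeros((H, W), dtype=np.float64)
    covered = den > 0
    out[covered] = num[covered] / den[covered]
    return out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def lymphangiography(
    volume: RepeatedBScanVolume, params: Optional[OlagParams] = None
) -> OlagResult:
    """Run the full lymphatic-mapping chain on a repeated-B-scan volume.

    compensate -> surface -> EDJ -> flatten -> (equalize) -> sMIP -> mask,
    per configured dermal slab.
    """
    if params is None:
        params = OlagParams()
    pitch = volume.protocol.axial_pitch_um

    intensity = volume.structural_intensity()
    comp, zero_flags = compensate_attenuation(intensity, params.exponent)
    amp = volume.mean_amplitude_volume()
    surface, s_flags = detect_surface(amp)
    edj, e_flags = segment_edj(
        comp, surface, axial_pitch_um=pitch, window_um=params.window_um
    )
    col_flags = zero_flags | s_flags | e_flags
    surfaces = SurfaceMaps(surface=surface, edj=edj, flags=col_flags)

    flat, valid, target = flatten(comp, edj)

    slabs: List[SlabResult] = []
    for slab in params.slabs_um:
        enface = smip(
            flat,
            flatten_index=target,
            slab_um=slab,
            axial_pitch_um=pitch,
            k_frac=params.k_frac,
            equalize=params.equalize,
        )
        mask = extract_lymph_mask(
            enface,
            valid=~col_flags,
            method=params.threshold,
            percentile=params.percentile,
            min_size=params.min_size,
            elongation_ratio=params.elongation_ratio,
            smooth_size=params.mask_smooth_size,
            smooth_sigma=params.mask_smooth_sigma,
        )
        slabs.append(SlabResult(slab_um=slab, enface=enface, mask=mask))
    return OlagResult(
        surfaces=surfaces, slabs=slabs, flatten_index=target, params=params
    )
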