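"""Vessel-density quantification and longitudinal reporting.

Vessel area density is the fraction of valid en-face pixels classified as
vessel, in percent — the standard OCT-angiography density metric.  The
module also binarizes flow projections, computes Dice overlap against
reference masks, and assembles tidy longitudinal tables (timepoint x slab
x metric) for monitoring studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "DensityReport",
    "vessel_area_density",
    "binarize_angiogram",
    "dice",
    "longitudinal_report",
]


@dataclass
class DensityReport:
    """Densities measured at one timepoint.

    ``lymph_density_pct`` maps slab bounds (um below the EDJ) to lymphatic
    vessel area density; ``microvascular_density_pct`` is the density of
    the binarized flow projection.  ``parameters`` snapshots the settings
    that produced the masks.
    """

    timepoint: str
    lymph_density_pct: Dict[Tuple[float, float], float]
    microvascular_density_pct: Optional[float] = None
    parameters: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for slab, v in self.lymph_density_pct.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"density for slab {slab} out of [0, 100]: {v}")
        if self.microvascular_density_pct is not None and not (
            0.0 <= self.microvascular_density_pct <= 100.0
        ):
            raise ValueError("microvascular density out of [0, 100]")


def vessel_area_density(
    mask: np.ndarray, valid: Optional[np.ndarray] = None
) -> float:
    """Percent of valid en-face pixels inside the vessel mask."""
    mask = np.asarray(mask, dtype=bool)
    if valid is None:
        valid = np.ones(mask.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != mask.shape:
        raise ValueError("mask and validity map shapes differ")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid pixels: density undefined")
    return 100.0 * float((mask & valid).sum()) / n_valid


def binarize_angiogram(
    enface: np.ndarray,
    method: str = "otsu",
    percentile: float = 90.0,
    valid: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, bool]:
    """Threshold an en-face flow projection into a vessel mask.

    Above-threshold pixels are vessel.  Returns ``(mask, flagged)``;
    a constant image cannot be thresholded and yields an empty, flagged
    mask.
    """
    img = np.asarray(enface, dtype=np.float64)
    if not np.isfinite(img[np.isfinite(img)]).size and valid is None:
        raise ValueError("empty image")
    if valid is None:
        valid = np.isfinite(img)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(img)
    vals = img[valid]
    if vals.size == 0 or np.ptp(vals) == 0:
        warnings.warn("constant flow projection: returning empty vessel mask")
        return np.zeros(img.shape, dtype=bool), True
    if method == "otsu":
        thr = float(threshold_otsu(vals))
    elif method == "percentile":
        thr = float(np.percentile(vals, percentile))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return valid & (img > thr), False


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks agree (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def longitudinal_report(reports: Sequence[DensityReport]) -> pd.DataFrame:
    """Tidy table of densities across timepoints.

    One row per (timepoint, slab) for lymphatic density plus one row per
    timepoint for microvascular density; rows are sorted by timepoint then
    slab.  All reports must share the same slab configuration.
    """
    if len(reports) == 0:
        raise ValueError("need at least one report")
    slabs0 = sorted(reports[0].lymph_density_pct.keys())
    rows = []
    for rep in reports:
        if sorted(rep.lymph_density_pct.keys()) != slabs0:
            raise ValueError(
                f"inconsistent slab configuration at timepoint {rep.timepoint!r}"
            )
        for slab in slabs0:
            rows.append(
                {
                    "timepoint": rep.timepoint,
                    "slab_um": f"{slab[0]:g}-{slab[1]:g}",
                    "metric": "lymph_density_pct",
                    "value": rep.lymph_density_pct[slab],
                }
            )
        if rep.microvascular_density_pct is not None:
            rows.append(
                {
                    "timepoint": rep.timepoint,
                    "slab_um": "all",
                    "metric": "microvascular_density_pct",
                    "value": rep.microvascular_density_pct,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["timepoint", "metric", "slab_um"]).reset_index(
        drop=True
    )
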