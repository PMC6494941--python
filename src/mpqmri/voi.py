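"""Whole-tumor VOI assembly, histogram summaries and fat-dominance calls.

Per-slice tumor ROIs are unioned into a volume of interest, transferred to
each parameter map's grid by nearest-neighbour resampling, and summarised
by first-order histogram statistics (median, mean, SD, 10th/25th/75th/90th
centiles, skew, kurtosis) plus tumor volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .fitting import ParameterMap

__all__ = [
    "VOIMask",
    "VOISummary",
    "NoValidVoxelsError",
    "assemble_voi",
    "summarize_map",
    "classify_fat_dominant",
]


class NoValidVoxelsError(ValueError):
    """Raised when a VOI contains no valid fitted voxels for a parameter."""


@dataclass
class VOIMask:
    """Whole-tumor mask on a named image grid."""

    mask: np.ndarray  # 3D bool
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("VOI mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass
class VOISummary:
    """First-order histogram summary of one parameter over the VOI.

    Statistics are computed over valid fitted voxels only; ``volume_cm3``
    counts every VOI voxel regardless of fit validity.  Centiles use linear
    interpolation between order statistics; skew and kurtosis are the
    standardized 3rd/4th sample moments (Pearson convention: a normal
    distribution has kurtosis 3); both are NaN for a constant map.
    """

    parameter: str
    median: float
    mean: float
    sd: float
    p10: float
    p25: float
    p75: float
    p90: float
    skew: float
    kurtosis: float
    n_voxels: int
    n_voi_voxels: int
    volume_cm3: float


def assemble_voi(
    slice_rois: Mapping[int, np.ndarray],
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    target_shape: tuple[int, int, int] | None = None,
    target_voxel_size: tuple[float, float, float] | None = None,
    slice_axis: int = 2,
) -> VOIMask:
    """Union per-slice ROIs into a VOI, resampling onto a target grid.

    ``slice_rois`` maps slice index (along ``slice_axis``) to a 2D boolean
    ROI on the source grid.  When a target grid is given, the union is
    transferred by nearest-neighbour lookup of voxel centres, assuming the
    two grids share a field of view.
    """
    mask = np.zeros(grid_shape, dtype=bool)
    any_voxels = False
    for z, roi in slice_rois.items():
        roi = np.asarray(roi, dtype=bool)
        sl = [slice(None)] * 3
        sl[slice_axis] = z
        if roi.shape != mask[tuple(sl)].shape:
            raise ValueError(f"slice ROI {z} does not match the source grid")
        mask[tuple(sl)] |= roi
        any_voxels = any_voxels or roi.any()
    if not any_voxels:
        raise ValueError("union of slice ROIs is empty")

    if target_shape is None or tuple(target_shape) == tuple(grid_shape):
        return VOIMask(mask=mask, voxel_size=tuple(voxel_size))

    # voxel-centre aligned nearest-neighbour transfer (shared FOV)
    src_idx = []
    for ax in range(3):
        ratio = grid_shape[ax] / target_shape[ax]
        centres = (np.arange(target_shape[ax]) + 0.5) * ratio - 0.5
        src_idx.append(np.clip(np.rint(centres).astype(int), 0, grid_shape[ax] - 1))
    resampled = mask[np.ix_(*src_idx)]
    if not resampled.any():
        raise ValueError("VOI is empty after resampling onto the target grid")
    vs = tuple(target_voxel_size) if target_voxel_size is not None else tuple(voxel_size)
    return VOIMask(mask=resampled, voxel_size=vs)


def summarize_map(pmap: ParameterMap, voi: VOIMask) -> VOISummary:
    """Histogram summary of ``pmap`` over the VOI."""
    if pmap.values.shape != voi.mask.shape:
        raise ValueError("parameter map and VOI must share a grid")
    sel = voi.mask & pmap.valid_mask
    vals = pmap.values[sel]
    if vals.size == 0:
        raise NoValidVoxelsError(f"no valid {pmap.parameter} voxels in the VOI")

    p10, p25, med, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if sd > 0:
        skew = float(stats.skew(vals, bias=True))
        kurt = float(stats.kurtosis(vals, fisher=False, bias=True))
    else:
        skew = float("nan")
        kurt = float("nan")
    return VOISummary(
        parameter=pmap.parameter,
        median=float(med),
        mean=float(np.mean(vals)),
        sd=sd,
        p10=float(p10),
        p25=float(p25),
        p75=float(p75),
        p90=float(p90),
        skew=skew,
        kurtosis=kurt,
        n_voxels=int(vals.size),
        n_voi_voxels=voi.n_voxels,
        volume_cm3=voi.n_voxels * voi.voxel_volume_cm3,
    )


def classify_fat_dominant(ff, threshold: float = 0.80) -> bool:
    """Exclude-from-diffusion/R2*-analysis flag for fat-dominant tumors.

    ``ff`` is a mean fat fraction in [0, 1] (or a VOISummary of FF, whose
    mean is used).  Returns True (exclude) iff FF strictly exceeds the
    threshold; a tumor at exactly 80% fat is retained.
    """
    if isinstance(ff, VOISummary):
        ff = ff.mean
    ff = float(ff)
    if not 0.0 <= ff <= 1.0:
        raise ValueError("fat fraction must lie in [0, 1]")
    return ff > threshold
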