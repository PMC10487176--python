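"""Bone segmentation: median denoise, Bernsen local threshold, connectivity
filter, and a parametric distal-condyle crop.

The chain mirrors a classical CT bone-isolation recipe: a median filter
(spherical radius, default 2 voxels) removes noise, a contrast-based local
threshold (Bernsen rule, default 50-voxel cubic window) binarises, and a
connected-component filter keeps the bone as the largest foreground object.
The diaphysis is then removed by an axis-aligned cut plane placed at a
stated fraction of the bone's extent along its long (proximodistal) axis —
a reproducible stand-in for interactive cropping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .volume import BoneMask, VoxelGrid

__all__ = ["SegmentationParams", "BoneSegmenter", "median_denoise",
           "local_threshold", "largest_component", "crop_condyle",
           "segment_bone", "dice"]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentationParams:
    median_radius: int = 2           # voxels, spherical neighbourhood
    window: int = 50                 # voxels, cubic Bernsen window
    contrast_threshold: float | None = None  # grey units; None = auto
    connectivity: int = 26
    cut_fraction: float = 0.5        # fraction of long-axis extent kept (distal)
    slice_wise: bool = False         # 2-D per-slice threshold windows

    def __post_init__(self) -> None:
        if self.median_radius < 1:
            raise ValueError("median radius must be >= 1")
        if self.window < 3:
            raise ValueError("local window must be >= 3 voxels")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if not 0.0 < self.cut_fraction <= 1.0:
            raise ValueError("cut fraction must lie in (0, 1]")


def _ball_offsets(radius: int) -> list[tuple[int, int, int]]:
    r = int(radius)
    offs = []
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            for dk in range(-r, r + 1):
                if di * di + dj * dj + dk * dk <= r * r:
                    offs.append((di, dj, dk))
    return offs


def median_denoise(grid: VoxelGrid, radius: int = 2) -> VoxelGrid:
    """Median over a spherical voxel neighbourhood; truncated at the edges.

    For radius 2 the neighbourhood has 33 voxels.  Edge voxels take the
    median over the in-volume part of the neighbourhood only (even counts
    average the two central values, the numpy median convention).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    v = np.asarray(grid.values, dtype=np.float64)
    r = int(radius)
    offsets = _ball_offsets(r)
    padded = np.pad(v, r, mode="constant", constant_values=np.nan)
    nx, ny, nz = v.shape
    stack = np.empty((len(offsets), nx, ny, nz), dtype=np.float64)
    for n, (di, dj, dk) in enumerate(offsets):
        stack[n] = padded[r + di:r + di + nx, r + dj:r + dj + ny, r + dk:r + dk + nz]
    return grid.with_values(np.nanmedian(stack, axis=0))


def local_threshold(grid: VoxelGrid, window: int = 50,
                    contrast_threshold: float | None = None,
                    slice_wise: bool = False) -> BoneMask:
    """Bernsen contrast-based local threshold.

    Per voxel, with ``lo``/``hi`` the min/max over the centred cubic window
    (truncated at edges): if ``hi - lo >= contrast_threshold`` the voxel is
    foreground when its value >= (hi+lo)/2; otherwise the whole low-contrast
    region is foreground only when its midgrey (hi+lo)/2 exceeds the global
    mid-grey (strictly, so a uniform image yields an empty mask).

    ``contrast_threshold=None`` uses half the robust global range
    (percentiles 0.5–99.5), a value that sits between the within-bone
    cortical/trabecular contrast and the bone/background contrast.
    """
    if window < 3:
        raise ValueError("window must be >= 3 voxels")
    v = np.asarray(grid.values, dtype=np.float64)
    size = (window, window, 1) if slice_wise else window
    # replicate-padding preserves truncated-window min/max semantics exactly
    lo = ndimage.minimum_filter(v, size=size, mode="nearest")
    hi = ndimage.maximum_filter(v, size=size, mode="nearest")
    if contrast_threshold is None:
        p_lo, p_hi = np.percentile(v, [0.5, 99.5])
        contrast_threshold = max(0.5 * (p_hi - p_lo), 1e-9)
    mid = 0.5 * (hi + lo)
    global_mid = 0.5 * (float(v.min()) + float(v.max()))
    high_contrast = (hi - lo) >= contrast_threshold
    mask = np.where(high_contrast, v >= mid, mid > global_mid)
    return BoneMask.like(grid, mask)


def largest_component(mask: BoneMask, connectivity: int = 26) -> BoneMask:
    """Keep only the largest connected foreground component.

    Size ties break to the component containing the lowest minimal linear
    (C-order flat) index.  An empty input yields an empty output.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask.values, structure=structure)
    if n == 0:
        return mask.with_values(np.zeros(mask.shape, dtype=bool))
    sizes = ndimage.sum_labels(np.ones(mask.shape), labels, index=np.arange(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        flat = labels.ravel()
        first = [np.flatnonzero(flat == lbl)[0] for lbl in best]
        winner = int(best[int(np.argmin(first))])
    else:
        winner = int(best[0])
    return mask.with_values(labels == winner)


def crop_condyle(mask: BoneMask, cut_fraction: float,
                 distal_end: str = "auto") -> BoneMask:
    """Retain the distal ``cut_fraction`` of the bone along its long axis.

    The long axis is the bounding-box axis of maximal physical extent; the
    cut plane is axis-aligned.  ``distal_end`` picks which end of that axis
    is distal: 'low', 'high', or 'auto' (the end whose terminal quarter of
    slices holds more mask voxels — the bulkier condyle; ties go 'high').
    """
    if mask.count == 0:
        raise ValueError("cannot crop an empty mask")
    if not 0.0 < cut_fraction <= 1.0:
        raise ValueError("cut fraction must lie in (0, 1]")
    if distal_end not in ("auto", "low", "high"):
        raise ValueError("distal_end must be 'auto', 'low' or 'high'")
    idx = np.nonzero(mask.values)
    los = [int(i.min()) for i in idx]
    his = [int(i.max()) for i in idx]
    extents_mm = [(hi - lo + 1) * s for lo, hi, s in zip(los, his, mask.spacing)]
    axis = int(np.argmax(extents_mm))
    lo, hi = los[axis], his[axis]
    n_slices = hi - lo + 1

    counts = np.moveaxis(mask.values, axis, 0)[lo:hi + 1].reshape(n_slices, -1).sum(axis=1)
    if distal_end == "auto":
        q = max(1, n_slices // 4)
        distal_end = "high" if counts[-q:].sum() >= counts[:q].sum() else "low"

    keep = int(round(cut_fraction * n_slices))
    keep = min(max(keep, 1), n_slices)
    out = np.zeros(mask.shape, dtype=bool)
    sel = [slice(None)] * 3
    if distal_end == "high":
        sel[axis] = slice(hi - keep + 1, hi + 1)
    else:
        sel[axis] = slice(lo, lo + keep)
    out[tuple(sel)] = True
    out &= mask.values
    if not out.any():
        raise ValueError("cut plane removed all voxels")
    return mask.with_values(out)


def segment_bone(ct: VoxelGrid, params: SegmentationParams | None = None) -> BoneMask:
    """Full isolation chain: median -> Bernsen threshold -> largest component."""
    params = params or SegmentationParams()
    den = median_denoise(ct, params.median_radius)
    mask = local_threshold(den, params.window, params.contrast_threshold,
                           params.slice_wise)
    return largest_component(mask, params.connectivity)


def dice(a: BoneMask, b: BoneMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    inter = np.count_nonzero(a.values & b.values)
    total = a.count + b.count
    return 2.0 * inter / total if total else np.nan


class BoneSegmenter(BaseEstimator):
    """Estimator wrapper for the segmentation chain.

    ``transform`` runs median -> local threshold -> largest component;
    ``crop`` applies the distal cut plane on the resulting mask.
    """

    def __init__(self, median_radius: int = 2, window: int = 50,
                 contrast_threshold: float | None = None,
                 connectivity: int = 26, cut_fraction: float = 0.5,
                 slice_wise: bool = False, distal_end: str = "auto"):
        self.median_radius = median_radius
        self.window = window
        self.contrast_threshold = contrast_threshold
        self.connectivity = connectivity
        self.cut_fraction = cut_fraction
        self.slice_wise = slice_wise
        self.distal_end = distal_end

    def _params(self) -> SegmentationParams:
        return SegmentationParams(self.median_radius, self.window,
                                  self.contrast_threshold, self.connectivity,
                                  self.cut_fraction, self.slice_wise)

    def fit(self, ct: VoxelGrid | None = None, y=None):
        self._params()  # validate
        self.is_fitted_ = True
        return self

    def transform(self, ct: VoxelGrid) -> BoneMask:
        return segment_bone(ct, self._params())

    def crop(self, mask: BoneMask) -> BoneMask:
        return crop_condyle(mask, self.cut_fraction, self.distal_end)
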