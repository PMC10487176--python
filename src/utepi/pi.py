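"""Porosity-index (PI) maps from dual-echo UTE volumes.

PI is the ratio of the long-echo to the short-echo intensity, times 100.
Short-T2* collagen-bound water has fully decayed at the long echo, so the
ratio rises with the pore-water fraction, i.e. with porosity.  The map is
defined only where the short echo exceeds a background floor; other voxels
carry NaN and are excluded by the validity mask.  Values above 100 % (noise)
are kept and only reported in the diagnostics — silent clipping would bias
downstream regression slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BoneMask, VoxelGrid

__all__ = ["PIMap", "compute_pi", "pi_diagnostics", "estimate_background_sd"]


@dataclass
class PIMap:
    """PI values in % (NaN where invalid) plus the validity mask."""

    values: VoxelGrid
    valid: BoneMask

    def __post_init__(self) -> None:
        if not self.values.same_geometry(self.valid):
            raise ValueError("PI values and validity mask geometries differ")

    @property
    def grid(self) -> VoxelGrid:
        return self.values


def estimate_background_sd(grid: VoxelGrid, patch: int = 8) -> float:
    """Noise SD estimate: median of the per-patch SDs of the 8 corner patches."""
    v = grid.values
    p = [min(patch, s) for s in v.shape]
    sds = []
    for sx in (slice(0, p[0]), slice(-p[0], None)):
        for sy in (slice(0, p[1]), slice(-p[1], None)):
            for sz in (slice(0, p[2]), slice(-p[2], None)):
                sds.append(float(v[sx, sy, sz].std()))
    return float(np.median(sds))


def compute_pi(echo1: VoxelGrid, echo2: VoxelGrid,
               floor: float | None = None) -> PIMap:
    """PI = 100 * echo2 / echo1 where echo1 > floor; NaN elsewhere.

    ``floor`` defaults to 5x the background noise SD estimated from the
    corner patches of the short-echo volume.
    """
    if not echo1.same_geometry(echo2):
        raise ValueError("echo volumes do not share the same geometry")
    if floor is None:
        floor = 5.0 * estimate_background_sd(echo1)
    if floor < 0:
        raise ValueError("floor must be non-negative")
    e1, e2 = echo1.values, echo2.values
    valid = e1 > floor
    pi = np.full(e1.shape, np.nan)
    pi[valid] = 100.0 * e2[valid] / e1[valid]
    return PIMap(values=echo1.with_values(pi), valid=BoneMask.like(echo1, valid))


def pi_diagnostics(pi: PIMap, mask: BoneMask | None = None) -> dict:
    """Summary of a PI map over a mask (default: the validity mask)."""
    if mask is None:
        sel = pi.valid.values
    else:
        if mask.shape != pi.values.shape:
            raise ValueError("mask geometry does not match the PI map")
        sel = mask.values
    if not np.any(sel):
        raise ValueError("empty mask")
    vals = pi.values.values[sel]
    defined = vals[~np.isnan(vals)]
    frac_invalid = 1.0 - defined.size / vals.size
    if defined.size == 0:
        return {"n": int(vals.size), "n_valid": 0, "mean": np.nan,
                "median": np.nan, "sd": np.nan, "frac_invalid": 1.0,
                "frac_above_100": np.nan}
    return {
        "n": int(vals.size),
        "n_valid": int(defined.size),
        "mean": float(defined.mean()),
        "median": float(np.median(defined)),
        "sd": float(defined.std(ddof=1)) if defined.size > 1 else 0.0,
        "frac_invalid": float(frac_invalid),
        "frac_above_100": float((defined > 100.0).mean()),
    }
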