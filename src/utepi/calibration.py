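"""QCT grey-value to bone-mineral-density calibration.

CT grey values are mapped to a BMD scale (mg HA/cm^3) by a linear
transformation fitted on the calibration-phantom inserts: ordinary least
squares of known insert density on per-insert mean grey.  With two inserts
the fit is the exact two-point line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .volume import BoneMask, VoxelGrid

__all__ = ["CalibrationModel", "QCTCalibrator", "fit_calibration",
           "apply_calibration", "detect_insert_rods"]


@dataclass
class CalibrationModel:
    """Linear grey -> BMD map ``density = slope * grey + intercept``."""

    slope: float
    intercept: float
    insert_table: pd.DataFrame = field(repr=False, default=None)
    r_squared: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("calibration slope must be finite and nonzero")

    def predict(self, grey):
        return self.slope * np.asarray(grey, dtype=float) + self.intercept

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"slope: {self.slope!r}\n")
            fh.write(f"intercept: {self.intercept!r}\n")
            fh.write(f"r_squared: {self.r_squared!r}\n")

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        vals = {}
        with open(path) as fh:
            for line in fh:
                key, _, raw = line.partition(":")
                vals[key.strip()] = float(raw)
        return cls(vals["slope"], vals["intercept"], r_squared=vals.get("r_squared", np.nan))


class QCTCalibrator(BaseEstimator, TransformerMixin):
    """Estimator wrapper around the phantom calibration.

    Parameters
    ----------
    clamp_negative : bool, default False
        Clamp calibrated BMD below 0 to 0.  Off by default: retaining
        noise-driven negative values keeps downstream voxel-wise regression
        unbiased.
    """

    def __init__(self, clamp_negative: bool = False):
        self.clamp_negative = clamp_negative

    def fit(self, ct: VoxelGrid, inserts: list[tuple[BoneMask, float]]):
        self.model_ = fit_calibration(ct, inserts)
        self.slope_ = self.model_.slope
        self.intercept_ = self.model_.intercept
        return self

    def transform(self, ct: VoxelGrid) -> VoxelGrid:
        if not hasattr(self, "model_"):
            raise RuntimeError("QCTCalibrator is not fitted")
        return apply_calibration(ct, self.model_, clamp_negative=self.clamp_negative)


def fit_calibration(ct: VoxelGrid,
                    inserts: list[tuple[BoneMask, float]]) -> CalibrationModel:
    """OLS of insert density on per-insert mean grey value.

    Requires at least two inserts with distinct densities, non-empty and
    pairwise disjoint masks, and non-degenerate mean greys.
    """
    if len(inserts) < 2:
        raise ValueError("need at least 2 calibration inserts")
    greys, densities = [], []
    combined = np.zeros(ct.shape, dtype=int)
    for mask, density in inserts:
        if mask.count == 0:
            raise ValueError("empty insert mask")
        if mask.shape != ct.shape:
            raise ValueError("insert mask geometry does not match the CT volume")
        combined += mask.values.astype(int)
        greys.append(float(ct.values[mask.values].mean()))
        densities.append(float(density))
    if np.max(combined) > 1:
        raise ValueError("insert masks overlap")
    if len(set(densities)) < 2:
        raise ValueError("insert densities are all equal")
    greys = np.asarray(greys)
    densities = np.asarray(densities)
    sxx = float(((greys - greys.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate insert greys: identical means for distinct densities")
    sxy = float(((greys - greys.mean()) * (densities - densities.mean())).sum())
    slope = sxy / sxx
    intercept = float(densities.mean() - slope * greys.mean())
    fitted = slope * greys + intercept
    residuals = densities - fitted
    syy = float(((densities - densities.mean()) ** 2).sum())
    r2 = 1.0 - float((residuals ** 2).sum()) / syy if syy > 0 else np.nan
    table = pd.DataFrame({"density": densities, "mean_grey": greys,
                          "fitted": fitted, "residual": residuals,
                          "n_voxels": [m.count for m, _ in inserts]})
    return CalibrationModel(slope, intercept, insert_table=table, r_squared=r2)


def apply_calibration(ct: VoxelGrid, model: CalibrationModel,
                      clamp_negative: bool = False) -> VoxelGrid:
    """Voxelwise BMD = slope * grey + intercept, geometry preserved."""
    bmd = model.predict(ct.values)
    if clamp_negative:
        np.clip(bmd, 0.0, None, out=bmd)
    return ct.with_values(bmd)


def detect_insert_rods(ct: VoxelGrid, densities: list[float],
                       background_grey: float | None = None,
                       min_voxels: int = 20) -> list[tuple[BoneMask, float]]:
    """Convenience detector for the synthetic rod geometry.

    Thresholds away the background, drops the largest connected component
    (the bone) and matches the remaining components to ``densities`` by
    mean grey rank.  Not part of the scientific contract: clinical phantom
    inserts should be supplied as explicit masks.
    """
    from scipy import ndimage

    v = ct.values
    if background_grey is None:
        background_grey = float(np.percentile(v, 50))
    fg = v > background_grey + 5 * max(1.0, v.std() * 0.05)
    labels, n = ndimage.label(fg)
    if n < len(densities) + 1:
        raise ValueError("could not find enough candidate components")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    candidates = [lbl for lbl in order[1:] if sizes[lbl - 1] >= min_voxels]
    if len(candidates) < len(densities):
        raise ValueError("could not find enough insert-sized components")
    candidates = candidates[:len(densities)]
    means = [float(v[labels == lbl].mean()) for lbl in candidates]
    by_grey = [c for _, c in sorted(zip(means, candidates))]
    out = []
    for density, lbl in zip(sorted(densities), by_grey):
        out.append((BoneMask.like(ct, labels == lbl), float(density)))
    return out
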