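"""Multi-resolution affine registration of the PI/MR volume onto CT.

The similarity metric is mutual information; optimisation runs coarse to
fine over an image pyramid (SimpleITK's registration framework with a
Mattes MI metric, full voxel sampling for determinism).  A manual rigid
pre-alignment is modelled as an explicit initial transform (identity by
default, which is adequate for the small misalignments the synthetic data
simulates).  The standalone :func:`mutual_information` implements the plain
joint-histogram MI (in bits) used for metric-level checks and sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from sklearn.base import BaseEstimator

from .pi import PIMap
from .volume import (AffineTransform, BoneMask, VoxelGrid, _to_sitk, resample)

__all__ = ["RegistrationConfig", "mutual_information", "register_affine",
           "align_pi_to_ct", "MutualInfoRegistration", "transform_errors"]


@dataclass
class RegistrationConfig:
    levels: int = 3                 # pyramid levels, downsampling 4/2/1
    bins: int = 32                  # MI histogram bins
    iterations: int = 400
    learning_rate: float = 2.0
    min_step: float = 1e-6
    tolerance: float = 1e-8         # gradient-magnitude convergence tolerance
    sampling_fraction: float = 0.25  # voxel fraction per iteration (seeded)
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("need at least one pyramid level")
        if self.bins < 8:
            raise ValueError("need at least 8 histogram bins")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError("sampling fraction must lie in (0, 1]")


def mutual_information(fixed: VoxelGrid, moving: VoxelGrid,
                       transform: AffineTransform | None = None,
                       bins: int = 32,
                       sample_mask: BoneMask | None = None) -> float:
    """Joint-histogram mutual information, in bits.

    The moving image is resampled onto the fixed grid through ``transform``
    (identity by default); the histogram is built over the overlap region.
    Returns 0 for a degenerate (constant) marginal.
    """
    f = np.asarray(fixed.values, dtype=float)
    m_orig = np.asarray(moving.values, dtype=float)
    # bin edges from the untransformed images: keeps the metric a smooth
    # function of the transform (data-dependent edges make it jagged)
    f_lo, f_hi = np.nanmin(f), np.nanmax(f)
    m_lo, m_hi = np.nanmin(m_orig), np.nanmax(m_orig)
    if f_hi == f_lo or m_hi == m_lo:
        return 0.0
    mov = resample(moving, transform, fixed, "linear", fill=np.nan)
    m = mov.values
    valid = ~np.isnan(m) & ~np.isnan(f)
    if sample_mask is not None:
        valid &= sample_mask.values
    if not valid.any():
        raise ValueError("empty overlap between fixed and transformed moving image")
    f, m = f[valid], np.clip(m[valid], m_lo, m_hi)
    if f.max() == f.min() or m.max() == m.min():
        return 0.0
    joint, _, _ = np.histogram2d(f, m, bins=[np.linspace(f_lo, f_hi, bins + 1),
                                             np.linspace(m_lo, m_hi, bins + 1)])
    p = joint / joint.sum()
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / np.outer(pf, pm)[nz])))


def _nan_to_zero(grid: VoxelGrid) -> VoxelGrid:
    v = np.asarray(grid.values, dtype=float)
    if np.isnan(v).any():
        return grid.with_values(np.nan_to_num(v, nan=0.0))
    return grid


def _polar_rotation(matrix: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(matrix)
    r = u @ vt
    if np.linalg.det(r) < 0:  # avoid reflections in the rigid stage
        u[:, -1] *= -1
        r = u @ vt
    return r


def _rigid_capture(f_img: sitk.Image, m_img: sitk.Image,
                   init: AffineTransform, center: np.ndarray,
                   config: RegistrationConfig) -> tuple[AffineTransform, dict]:
    """Multi-resolution rigid stage (Mattes MI, gradient descent)."""
    tx = sitk.Euler3DTransform()
    tx.SetCenter(tuple(center))
    R = _polar_rotation(init.matrix)
    tx.SetMatrix(tuple(R.flatten()))
    tx.SetTranslation(tuple(init.matrix @ center + init.translation - center))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.bins)
    if config.sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(config.sampling_fraction, config.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=config.learning_rate, minStep=config.min_step,
        numberOfIterations=config.iterations, relaxationFactor=0.7,
        gradientMagnitudeTolerance=config.tolerance)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (config.levels - 1 - i) for i in range(config.levels)]
    sigmas = [float(s // 2) for s in shrink]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(tx, inPlace=True)
    reg.Execute(f_img, m_img)

    metric = reg.GetMetricValue()
    if not np.isfinite(metric):
        raise RuntimeError("registration metric became non-finite")
    A = np.asarray(tx.GetMatrix()).reshape(3, 3)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    log = {"rigid_metric": float(metric),
           "rigid_iterations": int(reg.GetOptimizerIteration()),
           "stop_condition": reg.GetOptimizerStopConditionDescription(),
           "levels": shrink}
    return AffineTransform(A, t + c - A @ c), log


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    """12 affine parameters -> transform about ``center``.

    Parameters: translation (mm, 3), Euler rotations (deg, 3), scale
    deviations (3, scale = 1 + s), shears (3).
    """
    t = p[:3]
    ang = np.deg2rad(p[3:6])
    sc = 1.0 + p[6:9]
    sh = p[9:12]
    cx, cy, cz = np.cos(ang)
    sx, sy, sz = np.sin(ang)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Sh = np.array([[1, sh[0], sh[1]], [0, 1, sh[2]], [0, 0, 1]])
    M = Rz @ Ry @ Rx @ Sh @ np.diag(sc)
    return AffineTransform(M, center - M @ center + t)


def _foreground_mask(fixed: VoxelGrid, dilate: int = 6) -> BoneMask:
    """Dilated bright-foreground region of the fixed image.

    Restricting the metric to the anatomy plus a margin keeps the large
    uniform background from flattening the MI landscape.
    """
    from scipy import ndimage

    v = fixed.values
    p_lo, p_hi = np.percentile(v, [0.5, 99.5])
    fg = v > 0.5 * (p_lo + p_hi)
    if not fg.any() or fg.all():
        fg = np.ones(fixed.shape, dtype=bool)
    else:
        fg = ndimage.binary_dilation(fg, iterations=dilate)
    return BoneMask.like(fixed, fg)


def _powell_affine_refine(fixed: VoxelGrid, moving: VoxelGrid,
                          start: AffineTransform, center: np.ndarray,
                          config: RegistrationConfig) -> tuple[AffineTransform, float]:
    """Derivative-free refinement of all 12 affine parameters.

    Maximises the plain joint-histogram MI at full resolution (restricted
    to the fixed image's foreground neighbourhood) via a Powell search of
    the residual transform composed with ``start``; deterministic.
    """
    from scipy import optimize

    mask = _foreground_mask(fixed)

    def neg_mi(p: np.ndarray) -> float:
        t = _params_to_transform(p, center).compose(start)
        try:
            return -mutual_information(fixed, moving, t, bins=config.bins,
                                       sample_mask=mask)
        except ValueError:  # empty overlap: strongly penalise
            return 0.0

    steps = np.concatenate([[0.3] * 3, [0.5] * 3, [0.02] * 3, [0.02] * 3])
    res = optimize.minimize(
        neg_mi, np.zeros(12), method="Powell",
        options={"direc": np.diag(steps), "xtol": 1e-4, "ftol": 1e-7,
                 "maxiter": 3})
    return _params_to_transform(res.x, center).compose(start), float(-res.fun)


def register_affine(fixed: VoxelGrid, moving: VoxelGrid,
                    init: AffineTransform | None = None,
                    config: RegistrationConfig | None = None
                    ) -> tuple[AffineTransform, dict]:
    """Maximise MI over world-space affines, coarse to fine.

    Two stages, mirroring the classical rigid-then-affine recipe: a
    multi-resolution rigid capture (SimpleITK, Mattes MI), followed by a
    full-resolution Powell refinement of all 12 affine parameters against
    the plain joint-histogram MI.  Returns the transform mapping fixed-grid
    world points into the moving image's frame (the pull transform for
    :func:`resample`), plus a log with metric values and diagnostics.
    """
    config = config or RegistrationConfig()
    init = init or AffineTransform.identity()
    mov = _nan_to_zero(moving)
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(mov)
    center = fixed.center()

    rigid, log = _rigid_capture(f_img, m_img, init, center, config)
    result, mi = _powell_affine_refine(fixed, mov, rigid, center, config)
    log["final_metric"] = mi
    return result, log


def align_pi_to_ct(pi: PIMap, ct: VoxelGrid,
                   transform: AffineTransform) -> PIMap:
    """Resample a PI map onto the CT grid (values linear, validity nearest)."""
    values = resample(_nan_to_zero(pi.values), transform, ct, "linear", fill=0.0)
    valid = resample(pi.valid, transform, ct, "nearest", fill=0.0)
    out = values.values.copy()
    out[~valid.values] = np.nan
    return PIMap(values=ct.with_values(out), valid=valid)


def transform_errors(estimate: AffineTransform, truth: AffineTransform,
                     at_point) -> dict:
    """Translation (per axis, at a reference point) and rotation errors.

    The residual map ``estimate ∘ truth⁻¹`` would be the identity for a
    perfect recovery; its displacement at ``at_point`` gives the translation
    error and the polar-decomposition angle of its matrix the rotation error
    (degrees).
    """
    delta = estimate.compose(truth.inverse())
    p = np.asarray(at_point, dtype=float)
    disp = delta.apply(p) - p
    u, _, vt = np.linalg.svd(delta.matrix)
    rot = u @ vt
    angle = np.rad2deg(np.arccos(np.clip((np.trace(rot) - 1) / 2, -1, 1)))
    scales = np.linalg.svd(delta.matrix, compute_uv=False)
    return {"translation_mm": disp, "rotation_deg": float(angle),
            "scale_error": float(np.max(np.abs(scales - 1.0)))}


class MutualInfoRegistration(BaseEstimator):
    """Estimator wrapper: ``fit(fixed, moving)`` stores ``transform_``."""

    def __init__(self, levels: int = 3, bins: int = 32, iterations: int = 300,
                 learning_rate: float = 1.0, min_step: float = 1e-4,
                 tolerance: float = 1e-6, sampling_fraction: float = 1.0,
                 seed: int = 12345):
        self.levels = levels
        self.bins = bins
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.min_step = min_step
        self.tolerance = tolerance
        self.sampling_fraction = sampling_fraction
        self.seed = seed

    def _config(self) -> RegistrationConfig:
        return RegistrationConfig(self.levels, self.bins, self.iterations,
                                  self.learning_rate, self.min_step,
                                  self.tolerance, self.sampling_fraction,
                                  self.seed)

    def fit(self, fixed: VoxelGrid, moving: VoxelGrid,
            init: AffineTransform | None = None):
        self.transform_, self.log_ = register_affine(fixed, moving, init,
                                                     self._config())
        self.final_metric_ = self.log_["final_metric"]
        return self

    def transform(self, pi: PIMap, ct: VoxelGrid) -> PIMap:
        if not hasattr(self, "transform_"):
            raise RuntimeError("MutualInfoRegistration is not fitted")
        return align_pi_to_ct(pi, ct, self.transform_)
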