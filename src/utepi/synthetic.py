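"""Synthetic paired QCT / dual-echo UTE-MR studies of a condyle-like bone.

The generator emulates the statistical structure the analysis pipeline
assumes, with full ground truth:

* a condyle-shaped bone (ellipsoidal cap on a cylindrical shaft) with a
  cortical shell and a trabecular core, each carrying a smooth spatial
  porosity field φ ∈ [0, 1];
* bone mineral density negatively coupled to porosity,
  ``BMD = rho_max * (1 - coupling * φ) + noise``;
* a CT volume whose grey values are linear in BMD, with hydroxyapatite
  calibration rods of known density rendered beside the bone;
* two UTE echo volumes from a two-pool exponential T2* decay model
  (collagen-bound water, short T2*; pore water, long T2*), sampled on a
  coarser MR grid under a known rigid misalignment.

Everything is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .volume import AffineTransform, BoneMask, VoxelGrid, resample, write_volume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "SpecimenBundle",
    "make_condyle_masks",
    "make_porosity_field",
    "make_bmd_field",
    "render_ct",
    "render_mr_echoes",
    "two_pool_signal",
    "pi_closed_form",
    "generate_study",
    "iter_study",
    "default_misalignment",
]

DEFAULT_LIMBS = ("LF", "RF", "LH", "RH")


def default_misalignment(center=(13.1, 13.1, 19.0)) -> AffineTransform:
    """Small rigid CT<-MR misalignment: 5 deg about z plus a translation."""
    rot = AffineTransform.rotation(axis=2, degrees=5.0, center=center)
    return AffineTransform(rot.matrix, rot.translation + np.array([3.2, -1.5, 0.8]))


@dataclass
class PhantomSpec:
    """All tunable knobs of the synthetic study.

    Units: mm for geometry, mg HA/cm^3 for densities, ms for echo and
    relaxation times, scanner grey units for the CT model.
    """

    # grids
    ct_shape: tuple[int, int, int] = (96, 96, 96)
    ct_spacing: tuple[float, float, float] = (0.273, 0.273, 0.4)
    mr_shape: tuple[int, int, int] = (64, 64, 64)
    mr_spacing: tuple[float, float, float] = (0.66, 0.66, 0.66)

    # condyle geometry (long axis = z, cap at the high-z / distal end);
    # the cap is an ellipsoid with y semi-axis cap_aspect_y * cap_radius so
    # the bone is not rotationally symmetric about its long axis
    cap_radius_mm: float = 8.5
    cap_aspect_y: float = 0.8
    shaft_radius_mm: float = 5.5
    shaft_length_mm: float = 22.0
    shell_thickness_mm: float = 1.6

    # porosity field
    phi_cortical: float = 0.035
    phi_trabecular: float = 0.793
    phi_variation: float = 0.06
    phi_smoothness_mm: float = 1.5

    # BMD coupling
    rho_max: float = 1400.0
    coupling: float = 0.4
    bmd_noise_sd: float = 25.0

    # CT grey model
    g0: float = 40.0
    g1: float = 1.8
    ct_noise_sd: float = 10.0
    soft_tissue_grey: float = 60.0
    insert_densities: tuple[float, ...] = (0.0, 100.0, 400.0, 800.0)
    insert_radius_mm: float = 1.5

    # two-pool UTE model
    te_short_ms: float = 0.04
    te_long_ms: float = 2.52
    t2s_bound_ms: float = 0.39
    t2s_pore_ms: float = 10.0
    a_bound: float = 1.0
    a_pore: float = 1.0
    mr_noise_sd: float = 0.02
    noise_model: str = "gaussian"  # or "rician"

    # misalignment (CT world point sampled for each MR world point)
    misalignment: AffineTransform = field(default_factory=default_misalignment)

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_cortical <= 1.0 and 0.0 <= self.phi_trabecular <= 1.0):
            raise ValueError("porosity levels must lie in [0, 1]")
        if self.rho_max <= 0:
            raise ValueError("rho_max must be positive")
        if self.g1 == 0:
            raise ValueError("CT grey slope g1 must be nonzero")
        if not self.te_short_ms < self.te_long_ms:
            raise ValueError("TE_short must be strictly less than TE_long")
        if self.t2s_bound_ms <= 0 or self.t2s_pore_ms <= 0:
            raise ValueError("T2* constants must be positive")
        if not self.t2s_bound_ms < self.t2s_pore_ms:
            raise ValueError("bound-water T2* must be shorter than pore-water T2*")
        if len(set(self.insert_densities)) < 2:
            raise ValueError("need at least 2 distinct insert densities")
        if self.shell_thickness_mm >= self.cap_radius_mm:
            raise ValueError("shell thickness must be smaller than the cap radius")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    @classmethod
    def scaled(cls, factor: float, seed: int = 0, **overrides) -> "PhantomSpec":
        """A geometrically downscaled phantom (grids and bone shrink together).

        Useful for quick runs: ``factor=0.5`` halves grid shapes and all
        bone/insert dimensions so the anatomy still fills the field of view.
        Noise levels, densities and the MR signal model are unchanged.
        """
        base = cls(seed=seed)
        geom = dict(
            ct_shape=tuple(max(16, int(round(n * factor))) for n in base.ct_shape),
            mr_shape=tuple(max(12, int(round(n * factor))) for n in base.mr_shape),
            cap_radius_mm=base.cap_radius_mm * factor,
            shaft_radius_mm=base.shaft_radius_mm * factor,
            shaft_length_mm=base.shaft_length_mm * factor,
            shell_thickness_mm=max(base.shell_thickness_mm * factor, 0.9),
            insert_radius_mm=max(base.insert_radius_mm * factor, 0.8),
            phi_smoothness_mm=base.phi_smoothness_mm * factor,
        )
        geom.update(overrides)
        spec = cls(seed=seed, **geom)
        if "misalignment" not in overrides:
            center = spec.ct_grid().center()
            rot = AffineTransform.rotation(axis=2, degrees=5.0, center=center)
            spec.misalignment = AffineTransform(
                rot.matrix, rot.translation + factor * np.array([3.2, -1.5, 0.8]))
        return spec

    # -- derived geometry ---------------------------------------------------
    def ct_grid(self) -> VoxelGrid:
        return VoxelGrid(np.zeros(self.ct_shape), self.ct_spacing, (0.0, 0.0, 0.0))

    def mr_grid(self) -> VoxelGrid:
        ct_extent = np.asarray(self.ct_shape) * np.asarray(self.ct_spacing)
        mr_extent = np.asarray(self.mr_shape) * np.asarray(self.mr_spacing)
        origin = ct_extent / 2.0 - mr_extent / 2.0
        return VoxelGrid(np.zeros(self.mr_shape), self.mr_spacing, origin)

    def axis_center_xy(self) -> np.ndarray:
        ct_extent = np.asarray(self.ct_shape) * np.asarray(self.ct_spacing)
        return ct_extent[:2] / 2.0

    def cap_center_z(self) -> float:
        ct_extent_z = self.ct_shape[2] * self.ct_spacing[2]
        return ct_extent_z - self.cap_radius_mm - 2.0 * self.ct_spacing[2]

    def junction_z(self) -> float:
        """z of the cap/shaft junction (where the cap widens past the shaft)."""
        b = self.cap_aspect_y * self.cap_radius_mm
        if b <= self.shaft_radius_mm:
            raise ValueError("cap minor semi-axis must exceed the shaft radius")
        return self.cap_center_z() - self.cap_radius_mm * np.sqrt(
            1.0 - (self.shaft_radius_mm / b) ** 2)

    def condyle_cut_fraction(self) -> float:
        """Fraction of the bone's z-extent distal to the cap/shaft junction."""
        z_lo = self.cap_center_z() - self.shaft_length_mm
        z_hi = self.cap_center_z() + self.cap_radius_mm
        return float((z_hi - self.junction_z()) / (z_hi - z_lo))


@dataclass
class GroundTruth:
    porosity: VoxelGrid
    bmd: VoxelGrid
    bone_mask: BoneMask
    shell_mask: BoneMask
    condyle_mask: BoneMask
    insert_masks: list[tuple[BoneMask, float]]
    transform: AffineTransform  # maps CT world -> MR world (aligns MR onto CT)
    true_r: float  # voxelwise Pearson r of (BMD, ideal PI) inside the condyle


@dataclass
class SpecimenBundle:
    horse: str
    limb: str
    ct: VoxelGrid
    echo1: VoxelGrid
    echo2: VoxelGrid
    truth: GroundTruth
    spec: PhantomSpec
    excluded: bool = False


# ---------------------------------------------------------------------------
# Field construction

def make_condyle_masks(spec: PhantomSpec) -> dict[str, BoneMask]:
    """Bone / shell / core / condyle masks on the CT grid."""
    grid = spec.ct_grid()
    X, Y, Z = grid.world_coordinates()
    cx, cy = spec.axis_center_xy()
    cz = spec.cap_center_z()
    r2_xy = (X - cx) ** 2 + (Y - cy) ** 2

    a = spec.cap_radius_mm
    b = spec.cap_aspect_y * spec.cap_radius_mm
    cap = ((X - cx) ** 2 / a ** 2 + (Y - cy) ** 2 / b ** 2
           + (Z - cz) ** 2 / a ** 2) <= 1.0
    shaft = (r2_xy <= spec.shaft_radius_mm ** 2) \
        & (Z >= cz - spec.shaft_length_mm) & (Z <= cz)
    bone = cap | shaft

    dist = ndimage.distance_transform_edt(bone, sampling=grid.spacing)
    shell = bone & (dist <= spec.shell_thickness_mm)

    masks = {
        "bone": BoneMask.like(grid, bone),
        "shell": BoneMask.like(grid, shell),
        "core": BoneMask.like(grid, bone & ~shell),
        "condyle": BoneMask.like(grid, cap),
    }
    return masks


def make_porosity_field(spec: PhantomSpec,
                        rng: np.random.Generator | None = None
                        ) -> tuple[VoxelGrid, dict[str, BoneMask]]:
    """Porosity φ on the CT grid: shell ~ φ_c, core ~ φ_t, smooth variation."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    masks = make_condyle_masks(spec)
    grid = spec.ct_grid()
    bone = masks["bone"].values
    shell = masks["shell"].values

    phi = np.zeros(grid.shape)
    phi[shell] = spec.phi_cortical
    phi[bone & ~shell] = spec.phi_trabecular

    if spec.phi_variation > 0:
        sigma_vox = spec.phi_smoothness_mm / np.asarray(grid.spacing)
        noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma_vox)
        sd = noise.std()
        if sd > 0:
            phi[bone] += spec.phi_variation * (noise[bone] / sd)

    np.clip(phi, 0.0, 1.0, out=phi)
    phi[~bone] = 0.0
    return grid.with_values(phi), masks


def make_bmd_field(porosity: VoxelGrid, spec: PhantomSpec,
                   bone_mask: BoneMask,
                   rng: np.random.Generator | None = None) -> VoxelGrid:
    """BMD = rho_max * (1 - coupling * φ) + noise inside bone, clipped at 0."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    phi = porosity.values
    if np.nanmin(phi) < 0 or np.nanmax(phi) > 1:
        raise ValueError("porosity must lie in [0, 1]")
    bone = bone_mask.values
    bmd = np.zeros(porosity.shape)
    bmd[bone] = spec.rho_max * (1.0 - spec.coupling * phi[bone])
    if spec.bmd_noise_sd > 0:
        bmd[bone] += rng.normal(0.0, spec.bmd_noise_sd, size=int(bone.sum()))
    np.clip(bmd, 0.0, None, out=bmd)
    return porosity.with_values(bmd)


def _insert_rod_masks(spec: PhantomSpec, grid: VoxelGrid,
                      bone: np.ndarray) -> list[tuple[BoneMask, float]]:
    X, Y, Z = grid.world_coordinates()
    extent = np.asarray(grid.shape) * grid.spacing
    margin = spec.insert_radius_mm + 2.0 * max(grid.spacing[:2])
    corners = [(margin, margin), (extent[0] - margin, margin),
               (margin, extent[1] - margin), (extent[0] - margin, extent[1] - margin)]
    z_lo, z_hi = 0.2 * extent[2], 0.8 * extent[2]
    out: list[tuple[BoneMask, float]] = []
    for (cx, cy), density in zip(corners, spec.insert_densities):
        rod = ((X - cx) ** 2 + (Y - cy) ** 2 <= spec.insert_radius_mm ** 2) \
            & (Z >= z_lo) & (Z <= z_hi)
        if np.any(rod & bone):
            raise ValueError("calibration insert overlaps the bone geometry")
        out.append((BoneMask.like(grid, rod), float(density)))
    if len(out) < len(spec.insert_densities):
        raise ValueError("more insert densities than available rod positions (max 4)")
    return out


def render_ct(bmd: VoxelGrid, spec: PhantomSpec, bone_mask: BoneMask,
              rng: np.random.Generator | None = None
              ) -> tuple[VoxelGrid, list[tuple[BoneMask, float]]]:
    """CT grey = g0 + g1*BMD in bone, calibration rods in the corners."""
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    bone = bone_mask.values
    grey = np.full(bmd.shape, spec.soft_tissue_grey)
    grey[bone] = spec.g0 + spec.g1 * bmd.values[bone]
    inserts = _insert_rod_masks(spec, bmd, bone)
    for mask, density in inserts:
        grey[mask.values] = spec.g0 + spec.g1 * density
    if spec.ct_noise_sd > 0:
        grey = grey + rng.normal(0.0, spec.ct_noise_sd, size=grey.shape)
    return bmd.with_values(grey), inserts


def two_pool_signal(phi, te_ms: float, spec: PhantomSpec):
    """S(TE) = A_BW (1-φ) exp(-TE/T2*_BW) + A_PW φ exp(-TE/T2*_PW)."""
    phi = np.asarray(phi, dtype=float)
    return (spec.a_bound * (1.0 - phi) * np.exp(-te_ms / spec.t2s_bound_ms)
            + spec.a_pore * phi * np.exp(-te_ms / spec.t2s_pore_ms))


def pi_closed_form(phi, spec: PhantomSpec):
    """Noiseless porosity index (%) of the two-pool model at porosity φ."""
    return 100.0 * (two_pool_signal(phi, spec.te_long_ms, spec)
                    / two_pool_signal(phi, spec.te_short_ms, spec))


def render_mr_echoes(porosity: VoxelGrid, spec: PhantomSpec,
                     bone_mask: BoneMask,
                     rng: np.random.Generator | None = None
                     ) -> tuple[VoxelGrid, VoxelGrid]:
    """Dual-echo UTE volumes on the (misaligned) MR grid.

    The MR voxel at world point x samples the bone signal at
    ``misalignment(x)`` in CT world coordinates, so the returned volumes are
    shifted/rotated with respect to the CT frame; the transform that aligns
    them back onto CT is ``misalignment.inverse()`` (stored in GroundTruth).
    """
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    bone = bone_mask.values
    echoes = []
    for te in (spec.te_short_ms, spec.te_long_ms):
        signal = np.zeros(porosity.shape)
        signal[bone] = two_pool_signal(porosity.values[bone], te, spec)
        ideal = porosity.with_values(signal)
        echo = resample(ideal, spec.misalignment, spec.mr_grid(), "linear", fill=0.0)
        if spec.mr_noise_sd > 0:
            noise = rng.normal(0.0, spec.mr_noise_sd, size=echo.shape)
            if spec.noise_model == "rician":
                noise2 = rng.normal(0.0, spec.mr_noise_sd, size=echo.shape)
                echo = echo.with_values(np.hypot(echo.values + noise, noise2))
            else:
                echo = echo.with_values(echo.values + noise)
        else:
            echo = echo.with_values(echo.values)
        echoes.append(echo)
    return echoes[0], echoes[1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / denom) if denom > 0 else np.nan


def make_specimen(spec: PhantomSpec, horse: str = "horse1", limb: str = "LF",
                  excluded: bool = False) -> SpecimenBundle:
    """Generate one fully-characterised specimen from a spec."""
    root = np.random.default_rng(spec.seed)
    streams = root.spawn(4)
    porosity, masks = make_porosity_field(spec, streams[0])
    bmd = make_bmd_field(porosity, spec, masks["bone"], streams[1])
    ct, inserts = render_ct(bmd, spec, masks["bone"], streams[2])
    echo1, echo2 = render_mr_echoes(porosity, spec, masks["bone"], streams[3])

    condyle = masks["condyle"].values
    ideal_pi = pi_closed_form(porosity.values[condyle], spec)
    true_r = _pearson(bmd.values[condyle], ideal_pi)

    truth = GroundTruth(porosity=porosity, bmd=bmd, bone_mask=masks["bone"],
                        shell_mask=masks["shell"], condyle_mask=masks["condyle"],
                        insert_masks=inserts,
                        transform=spec.misalignment.inverse(), true_r=true_r)
    return SpecimenBundle(horse=horse, limb=limb, ct=ct, echo1=echo1,
                          echo2=echo2, truth=truth, spec=spec, excluded=excluded)


# ---------------------------------------------------------------------------
# Study generation

_SPEC_FIELDS = {f.name for f in fields(PhantomSpec)}


def _limb_spec(base: PhantomSpec, overrides: dict | None, horse: str,
               limb: str, seed: int) -> tuple[PhantomSpec, bool]:
    opts: dict = {}
    excluded = False
    if overrides:
        for key in (limb, (horse, limb), f"{horse}_{limb}"):
            if key in overrides:
                opts.update(overrides[key])
    excluded = bool(opts.pop("excluded", False))
    unknown = set(opts) - _SPEC_FIELDS
    if unknown:
        raise ValueError(f"unknown PhantomSpec overrides: {sorted(unknown)}")
    return replace(base, seed=seed, **opts), excluded


def iter_study(n_horses: int = 6, limbs: Sequence[str] = DEFAULT_LIMBS,
               spec: PhantomSpec | None = None, overrides: dict | None = None,
               seed: int = 0) -> Iterator[SpecimenBundle]:
    """Lazily generate the specimens of a study (memory-friendly).

    ``overrides`` maps a limb label, ``(horse, limb)`` tuple or
    ``"<horse>_<limb>"`` string to a dict of PhantomSpec field overrides;
    the special key ``excluded: True`` marks a specimen as excluded (it is
    still generated so the study layout matches, but flagged).
    """
    if n_horses < 1:
        raise ValueError("need at least one horse")
    if len(set(limbs)) != len(limbs):
        raise ValueError("duplicate limb labels")
    base = spec if spec is not None else PhantomSpec()
    idx = 0
    for h in range(1, n_horses + 1):
        horse = f"horse{h}"
        for limb in limbs:
            limb_seed = (seed * 104729 + idx * 7919) % (2 ** 31 - 1)
            sp, excluded = _limb_spec(base, overrides, horse, limb, limb_seed)
            yield make_specimen(sp, horse=horse, limb=limb, excluded=excluded)
            idx += 1


def generate_study(n_horses: int = 6, limbs: Sequence[str] = DEFAULT_LIMBS,
                   spec: PhantomSpec | None = None, overrides: dict | None = None,
                   seed: int = 0, out_dir=None) -> list[SpecimenBundle]:
    """Generate a full study; optionally write it to a directory layout.

    Layout: ``<out_dir>/<horse>_<limb>/{ct,echo1,echo2,truth_*}.nii.gz`` plus
    ``truth_transform.txt`` and a study-level ``manifest.csv``.
    """
    bundles = list(iter_study(n_horses, limbs, spec, overrides, seed))
    if out_dir is not None:
        write_study(bundles, out_dir)
    return bundles


def write_study(bundles: Sequence[SpecimenBundle], out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bundles:
        d = out_dir / f"{b.horse}_{b.limb}"
        d.mkdir(exist_ok=True)
        write_volume(b.ct, d / "ct.nii.gz")
        write_volume(b.echo1, d / "echo1.nii.gz")
        write_volume(b.echo2, d / "echo2.nii.gz")
        write_volume(b.truth.porosity, d / "truth_porosity.nii.gz")
        write_volume(b.truth.bmd, d / "truth_bmd.nii.gz")
        write_volume(b.truth.bone_mask, d / "truth_bone_mask.nii.gz")
        write_volume(b.truth.condyle_mask, d / "truth_condyle_mask.nii.gz")
        for i, (mask, density) in enumerate(b.truth.insert_masks):
            write_volume(mask, d / f"insert_{i}_{density:g}.nii.gz")
        b.truth.transform.save(d / "truth_transform.txt")
        rows.append({"horse": b.horse, "limb": b.limb,
                     "excluded": int(b.excluded), "true_r": b.truth.true_r,
                     "seed": b.spec.seed})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out_dir
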