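"""End-to-end workflow: simulate -> calibrate -> PI -> register -> segment ->
crop -> regress -> report.

The pipeline runs per specimen: the CT volume is calibrated to BMD with the
phantom inserts, segmented (median / local threshold / connectivity) and
cropped to the condyle; the dual-echo MR pair becomes a PI map, which is
registered to the CT (or aligned with a supplied ground-truth transform)
and resampled to CT resolution; finally PI is regressed on BMD voxel-wise
inside the condyle ROI.  Study-level runs aggregate the per-limb rows into
a :class:`~utepi.stats.StudyTable` with group summaries and comparisons.

A fully-resolved config is serialised next to every output for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import QCTCalibrator
from .pi import compute_pi
from .registration import RegistrationConfig, align_pi_to_ct, register_affine
from .segmentation import SegmentationParams, crop_condyle, segment_bone
from .stats import (RegressionResult, StudyTable, build_study_table,
                    load_table1, regress_specimen)
from .volume import AffineTransform, BoneMask, VoxelGrid, read_volume, write_volume

__all__ = ["PipelineConfig", "process_specimen", "run_specimen", "run_study",
           "reproduce_table1"]

log = logging.getLogger("utepi")


@dataclass
class PipelineConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    register_on: str = "pi"          # 'pi' (as acquired studies do) or 'echo1'
    use_truth_transform: bool = False
    init_transform: AffineTransform | None = None
    pi_floor: float | None = None    # None = auto from background noise
    clamp_negative_bmd: bool = False
    t_variant: str = "student"
    distal_end: str = "auto"
    scatter_sample: int = 2000       # voxels exported per specimen for plots
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.init_transform is not None:
            d["init_transform"] = self.init_transform.as_matrix4().tolist()
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("segmentation"):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if d.get("registration"):
            d["registration"] = RegistrationConfig(**d["registration"])
        if d.get("init_transform") is not None:
            d["init_transform"] = AffineTransform.from_matrix4(
                np.asarray(d["init_transform"]))
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def process_specimen(ct: VoxelGrid, echo1: VoxelGrid, echo2: VoxelGrid,
                     inserts: list[tuple[BoneMask, float]],
                     config: PipelineConfig | None = None,
                     truth_transform: AffineTransform | None = None,
                     cut_fraction: float | None = None,
                     horse: str = "", limb: str = "") -> dict:
    """Run the full per-specimen analysis in memory.

    Returns a dict with the calibrated ``bmd``, ``bone_mask``, ``roi``
    (condyle), MR-frame ``pi_mr``, the CT->MR ``transform`` used, the
    CT-frame ``pi_ct`` and the :class:`RegressionResult` row under
    ``result``.
    """
    config = config or PipelineConfig()

    calibrator = QCTCalibrator(clamp_negative=config.clamp_negative_bmd)
    calibrator.fit(ct, inserts)
    bmd = calibrator.transform(ct)

    bone = segment_bone(ct, config.segmentation)
    fraction = cut_fraction if cut_fraction is not None else config.segmentation.cut_fraction
    roi = crop_condyle(bone, fraction, config.distal_end)

    pi_mr = compute_pi(echo1, echo2, floor=config.pi_floor)

    reg_log: dict = {}
    if config.use_truth_transform:
        if truth_transform is None:
            raise ValueError("use_truth_transform requires a truth transform")
        transform = truth_transform
    else:
        moving = echo1 if config.register_on == "echo1" else pi_mr.values
        transform, reg_log = register_affine(ct, moving, config.init_transform,
                                             config.registration)
    pi_ct = align_pi_to_ct(pi_mr, ct, transform)

    result = regress_specimen(bmd, pi_ct, roi, horse=horse, limb=limb)
    return {"bmd": bmd, "bone_mask": bone, "roi": roi, "pi_mr": pi_mr,
            "transform": transform, "pi_ct": pi_ct, "result": result,
            "calibration": calibrator.model_, "registration_log": reg_log}


def _scatter_frame(art: dict, n: int, seed: int) -> pd.DataFrame:
    sel = art["roi"].values & art["pi_ct"].valid.values
    x = art["bmd"].values[sel]
    y = art["pi_ct"].values.values[sel]
    keep = ~np.isnan(y)
    x, y = x[keep], y[keep]
    if n and x.size > n:
        idx = np.random.default_rng(seed).choice(x.size, n, replace=False)
        x, y = x[idx], y[idx]
    return pd.DataFrame({"bmd": x, "pi": y})


def run_specimen(specimen_dir, config: PipelineConfig | None = None,
                 out_dir=None, horse: str = "", limb: str = "") -> RegressionResult:
    """Process one on-disk specimen directory; optionally write artifacts."""
    config = config or PipelineConfig()
    d = Path(specimen_dir)
    ct = read_volume(d / "ct.nii.gz")
    echo1 = read_volume(d / "echo1.nii.gz")
    echo2 = read_volume(d / "echo2.nii.gz")
    inserts = []
    for f in sorted(d.glob("insert_*.nii.gz")):
        density = float(f.name.rsplit("_", 1)[-1].removesuffix(".nii.gz"))
        m = read_volume(f)
        inserts.append((BoneMask(m.values > 0.5, m.spacing, m.origin, m.direction),
                        density))
    truth_t = None
    tfile = d / "truth_transform.txt"
    if tfile.exists():
        truth_t = AffineTransform.load(tfile)
    if not horse or not limb:
        parts = d.name.rsplit("_", 1)
        horse = horse or parts[0]
        limb = limb or (parts[1] if len(parts) > 1 else "")
    art = process_specimen(ct, echo1, echo2, inserts, config,
                           truth_transform=truth_t, horse=horse, limb=limb)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(art["bmd"], out / "bmd.nii.gz")
        write_volume(art["pi_ct"].values, out / "pi.nii.gz")
        write_volume(art["bone_mask"], out / "bone_mask.nii.gz")
        write_volume(art["roi"], out / "condyle_mask.nii.gz")
        art["transform"].save(out / "transform.txt")
        _scatter_frame(art, config.scatter_sample, config.seed).to_csv(
            out / "scatter.csv", index=False)
        config.save(out / "config_resolved.yaml")
        with open(out / "result.json", "w") as fh:
            json.dump(dataclasses.asdict(art["result"]), fh, indent=2)
    return art["result"]


def run_study(study_dir, config: PipelineConfig | None = None,
              out_dir=None) -> StudyTable:
    """Process every specimen listed in a study manifest.

    Excluded specimens are carried as explicit 'excluded' rows; a specimen
    whose processing fails is logged and recorded as excluded rather than
    aborting the study.
    """
    config = config or PipelineConfig()
    study_dir = Path(study_dir)
    manifest = study_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {study_dir}")
    rows = pd.read_csv(manifest)
    if rows.empty:
        raise ValueError(f"empty study manifest in {study_dir}")
    results: list[RegressionResult] = []
    for _, row in rows.iterrows():
        horse, limb = str(row["horse"]), str(row["limb"])
        if bool(row.get("excluded", False)):
            log.info("%s %s flagged excluded; skipping processing", horse, limb)
            results.append(RegressionResult(horse=horse, limb=limb, excluded=True))
            continue
        spec_out = Path(out_dir) / f"{horse}_{limb}" if out_dir else None
        try:
            results.append(run_specimen(study_dir / f"{horse}_{limb}", config,
                                        spec_out, horse=horse, limb=limb))
        except Exception:
            log.exception("specimen %s %s failed; recording as excluded", horse, limb)
            results.append(RegressionResult(horse=horse, limb=limb, excluded=True))
    if all(r.excluded for r in results):
        raise RuntimeError("all specimens failed or were excluded")
    table = build_study_table(results, variant=config.t_variant)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "study_table.csv")
        (out / "report.txt").write_text(table.report() + "\n")
        config.save(out / "config_resolved.yaml")
    return table


def reproduce_table1(variant: str = "student") -> dict:
    """Group statistics recomputed from the packaged per-limb table.

    Returns the overall r/slope summaries, the eight group means, and the
    four inter-limb comparisons, as plain floats.
    """
    table = load_table1()
    overall = table.overall()
    groups = table.group_summaries()
    comps = table.comparisons()
    return {
        "n_rows": len(table.results),
        "n_analyzable": int(len(table.analyzable)),
        "mean_r": overall["r"].mean, "sd_r": overall["r"].sd,
        "se_r": overall["r"].se,
        "min_r": overall["r"].min, "max_r": overall["r"].max,
        "mean_slope": overall["slope"].mean, "sd_slope": overall["slope"].sd,
        "se_slope": overall["slope"].se,
        "group_means": {k: s.mean for k, s in groups.items()},
        "comparisons": {k: {"t": c.t, "df": c.df, "p": c.p}
                        for k, c in comps.items()},
        "table": table,
    }
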