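"""Per-specimen voxel-wise BMD–PI regression and study-level group statistics.

Per specimen, PI (%) is regressed on BMD over all valid ROI voxels by
ordinary least squares; the Pearson correlation r, its two-tailed p-value
and a conventional strength label (Evans bands on |r|) summarise each limb.
Study-level reports aggregate the per-limb r values and slopes and compare
limb groups (fore vs hind, left vs right, LF vs RF, LH vs RH) with a
two-sample t-test preceded by a Jarque–Bera normality check.

The formulas are written out explicitly (sums of squares, t transforms of
r, JB from 1/n central moments) so they can be cross-checked against
independent library implementations; scipy supplies only the t and chi2
distribution tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .pi import PIMap
from .volume import BoneMask, VoxelGrid

__all__ = ["RegressionResult", "GroupSummary", "GroupComparison", "StudyTable",
           "regress_pairs", "regress_specimen", "correlation_label",
           "group_summary", "jarque_bera", "compare_groups",
           "build_study_table", "load_table1", "VoxelwiseRegression"]

FORELIMBS = ("LF", "RF")
HINDLIMBS = ("LH", "RH")
LEFT = ("LF", "LH")
RIGHT = ("RF", "RH")

_LABELS = ["very weak", "weak", "moderate", "strong", "very strong"]


@dataclass
class RegressionResult:
    """One row of the study table: a single limb's BMD–PI regression."""

    horse: str = ""
    limb: str = ""
    n_voxels: int = 0
    slope: float = np.nan      # PI % per BMD unit
    intercept: float = np.nan  # PI %
    slope_se: float = np.nan
    r: float = np.nan
    p: float = np.nan
    label: str = ""
    excluded: bool = False


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float     # sample SD, n-1 denominator
    se: float     # SD / sqrt(n)
    min: float
    max: float


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    variant: str
    jb_a: tuple[float, float]  # (statistic, p) per group
    jb_b: tuple[float, float]


def correlation_label(r: float) -> str:
    """Evans strength bands on |r| (rounded to 2 decimals first).

    [0, 0.20) very weak; [0.20, 0.40) weak; [0.40, 0.60) moderate;
    [0.60, 0.80) strong; [0.80, 1.00] very strong.
    """
    if not -1.0 <= r <= 1.0 + 1e-12:
        raise ValueError("r must lie in [-1, 1]")
    hundredths = math.floor(abs(r) * 100 + 0.5)  # half-away to 2 d.p.
    return _LABELS[min(hundredths // 20, 4)]


def regress_pairs(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with Pearson r and the two-tailed p for r.

    slope = Sxy/Sxx, intercept = ȳ - slope·x̄, SE(slope) = sqrt(RSS/(n-2)/Sxx),
    r = Sxy/sqrt(Sxx·Syy), p from t = r·sqrt((n-2)/(1-r²)) on n-2 df.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    if sxx == 0:
        raise ValueError("zero predictor variance")
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    rss = syy - slope * sxy
    rss = max(rss, 0.0)
    slope_se = math.sqrt(rss / (n - 2) / sxx)
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else np.nan
    if np.isnan(r) or abs(r) >= 1.0:
        p = 0.0 if not np.isnan(r) else np.nan
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return RegressionResult(n_voxels=n, slope=slope, intercept=intercept,
                            slope_se=slope_se, r=float(r), p=p,
                            label=correlation_label(float(r)) if not np.isnan(r) else "")


def regress_specimen(bmd: VoxelGrid, pi: PIMap, roi: BoneMask,
                     horse: str = "", limb: str = "") -> RegressionResult:
    """Voxel-wise OLS of PI (%) on BMD over valid ROI voxels."""
    if not bmd.same_geometry(pi.values):
        raise ValueError("BMD and PI grids do not share geometry")
    if roi.shape != bmd.shape:
        raise ValueError("ROI geometry does not match the BMD volume")
    sel = roi.values & pi.valid.values & ~np.isnan(pi.values.values)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"too few valid paired voxels in ROI ({n})")
    res = regress_pairs(bmd.values[sel], pi.values.values[sel])
    res.horse, res.limb = horse, limb
    return res


class VoxelwiseRegression(BaseEstimator):
    """Estimator wrapper: ``fit(bmd, pi, roi)`` stores slope_, r_, result_."""

    def fit(self, bmd: VoxelGrid, pi: PIMap, roi: BoneMask):
        self.result_ = regress_specimen(bmd, pi, roi)
        self.slope_ = self.result_.slope
        self.intercept_ = self.result_.intercept
        self.r_ = self.result_.r
        return self

    def predict(self, bmd):
        if not hasattr(self, "result_"):
            raise RuntimeError("VoxelwiseRegression is not fitted")
        return self.intercept_ + self.slope_ * np.asarray(bmd, dtype=float)


def group_summary(values, name: str = "") -> GroupSummary:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a group summary")
    sd = float(values.std(ddof=1))
    return GroupSummary(name=name, n=int(values.size), mean=float(values.mean()),
                        sd=sd, se=sd / math.sqrt(values.size),
                        min=float(values.min()), max=float(values.max()))


def jarque_bera(values) -> tuple[float, float]:
    """JB = n/6 (S² + (K-3)²/4) with moment-based skewness/kurtosis.

    S = m3/m2^{3/2}, K = m4/m2² from central moments with 1/n normalisation;
    the p-value comes from the chi-squared distribution with 2 df.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    d = x - x.mean()
    m2 = float((d ** 2).mean())
    if m2 == 0:
        raise ValueError("zero variance")
    s = float((d ** 3).mean()) / m2 ** 1.5
    k = float((d ** 4).mean()) / m2 ** 2
    jb = n / 6.0 * (s * s + (k - 3.0) ** 2 / 4.0)
    return jb, float(sps.chi2.sf(jb, 2))


def compare_groups(a, b, variant: str = "student",
                   name_a: str = "A", name_b: str = "B") -> GroupComparison:
    """Two-sample t-test (Student pooled or Welch), with per-group JB."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    if variant == "student":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return GroupComparison(group_a=name_a, group_b=name_b,
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           t=float(t), df=float(df), p=min(p, 1.0),
                           variant=variant,
                           jb_a=jarque_bera(a), jb_b=jarque_bera(b))


# ---------------------------------------------------------------------------
# Study table

@dataclass
class StudyTable:
    """Per-limb regression rows plus the group-level analyses."""

    results: list[RegressionResult]
    variant: str = "student"
    _frame: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        keys = [(r.horse, r.limb) for r in self.results]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (horse, limb) keys in study table")

    @property
    def frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame([{
                "horse": r.horse, "limb": r.limb, "n_voxels": r.n_voxels,
                "slope": r.slope, "slope_se": r.slope_se, "r": r.r,
                "p": r.p, "label": r.label, "excluded": r.excluded,
            } for r in self.results])
        return self._frame

    @property
    def analyzable(self) -> pd.DataFrame:
        return self.frame[~self.frame["excluded"]]

    def values_for(self, limbs) -> np.ndarray:
        df = self.analyzable
        return df.loc[df["limb"].isin(limbs), "r"].to_numpy()

    def overall(self) -> dict[str, GroupSummary]:
        df = self.analyzable
        return {"r": group_summary(df["r"], "r"),
                "slope": group_summary(df["slope"], "slope")}

    def group_summaries(self) -> dict[str, GroupSummary]:
        groups = {"fore": FORELIMBS, "hind": HINDLIMBS, "left": LEFT,
                  "right": RIGHT, "LF": ("LF",), "RF": ("RF",),
                  "LH": ("LH",), "RH": ("RH",)}
        return {name: group_summary(self.values_for(limbs), name)
                for name, limbs in groups.items()
                if self.values_for(limbs).size >= 2}

    def comparisons(self) -> dict[str, GroupComparison]:
        pairs = {
            "fore_vs_hind": (FORELIMBS, HINDLIMBS),
            "left_vs_right": (LEFT, RIGHT),
            "LF_vs_RF": (("LF",), ("RF",)),
            "LH_vs_RH": (("LH",), ("RH",)),
        }
        out: dict[str, GroupComparison] = {}
        self.skipped_comparisons: dict[str, str] = {}
        for name, (la, lb) in pairs.items():
            a, b = self.values_for(la), self.values_for(lb)
            if a.size < 2 or b.size < 2:
                self.skipped_comparisons[name] = (
                    f"skipped: group sizes {a.size} vs {b.size}")
                continue
            out[name] = compare_groups(a, b, self.variant,
                                       "+".join(la), "+".join(lb))
        return out

    def report(self) -> str:
        lines = [self.frame.to_string(index=False), ""]
        ov = self.overall()
        lines.append(f"overall r:     mean {ov['r'].mean:.4f}  SD {ov['r'].sd:.4f}"
                     f"  SE {ov['r'].se:.4f}  range [{ov['r'].min:.2f}, {ov['r'].max:.2f}]")
        lines.append(f"overall slope: mean {ov['slope'].mean:.5f}  SD {ov['slope'].sd:.5f}"
                     f"  SE {ov['slope'].se:.6f}")
        lines.append("")
        for name, s in self.group_summaries().items():
            lines.append(f"{name:>5}: n={s.n:2d}  mean r {s.mean:+.4f}  SD {s.sd:.4f}")
        lines.append("")
        for name, c in self.comparisons().items():
            lines.append(f"{name}: t={c.t:+.3f} df={c.df:.1f} p={c.p:.4f} ({c.variant})")
        for name, reason in getattr(self, "skipped_comparisons", {}).items():
            lines.append(f"{name}: {reason}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def build_study_table(results: list[RegressionResult],
                      variant: str = "student") -> StudyTable:
    if not results:
        raise ValueError("no regression results")
    return StudyTable(results=list(results), variant=variant)


def load_table1() -> StudyTable:
    """The packaged per-limb slope/SE/r table transcribed from the study."""
    with resources.files("utepi.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    results = []
    for _, row in df.iterrows():
        excluded = bool(row["excluded"])
        results.append(RegressionResult(
            horse=row["horse"], limb=row["limb"], n_voxels=0,
            slope=np.nan if excluded else float(row["slope"]),
            slope_se=np.nan if excluded else float(row["slope_se"]),
            r=np.nan if excluded else float(row["r"]),
            label="" if excluded else correlation_label(float(row["r"])),
            excluded=excluded))
    return build_study_table(results)
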