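"""Image-quality and BMD-agreement metrics for paired volumes.

All metrics operate over the in-mask voxels of a reference (ground-truth
QCT) and a test volume: MAD, PSNR, global single-window SSIM, NCC
(Pearson-style normalized cross-correlation), spatial nonuniformity (SNU)
over reference ROIs, the slope of the voxel-intensity regression,
Bland-Altman bias/limits of agreement, dental-arch intensity profiles,
paired t-tests and maxilla/mandible region aggregation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .volume import BACKGROUND_SENTINEL

#: default PSNR MAX and SSIM dynamic range: the normalization window width.
DEFAULT_DYNAMIC_RANGE = 4000.0


def _masked(ref, test, mask):
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError("ref/test shapes differ")
    if mask is None:
        m = np.ones(ref.shape, dtype=bool)
    else:
        m = np.asarray(mask).astype(bool)
        if m.shape != ref.shape:
            raise ValueError("mask shape differs")
    if not m.any():
        raise ValueError("empty mask")
    return ref[m], test[m]


def mad(ref, test, mask=None) -> float:
    """Mean absolute difference over in-mask voxels."""
    r, t = _masked(ref, test, mask)
    return float(np.mean(np.abs(r - t)))


def psnr(ref, test, mask=None, max_intensity: float = DEFAULT_DYNAMIC_RANGE) -> float:
    """20*log10(MAX / sqrt(MSE)); +inf when the images agree exactly."""
    r, t = _masked(ref, test, mask)
    mse = float(np.mean((r - t) ** 2))
    if mse == 0:
        return float("inf")
    return float(20.0 * np.log10(max_intensity / np.sqrt(mse)))


def ssim(
    ref,
    test,
    mask=None,
    c1: Optional[float] = None,
    c2: Optional[float] = None,
    dynamic_range: float = DEFAULT_DYNAMIC_RANGE,
) -> float:
    """Global single-window SSIM from masked means/variances/covariance.

    Stabilizers default to C1=(0.01 L)^2, C2=(0.03 L)^2 with L the
    dynamic range.
    """
    r, t = _masked(ref, test, mask)
    if c1 is None:
        c1 = (0.01 * dynamic_range) ** 2
    if c2 is None:
        c2 = (0.03 * dynamic_range) ** 2
    mu_r, mu_t = r.mean(), t.mean()
    var_r = r.var()
    var_t = t.var()
    cov = ((r - mu_r) * (t - mu_t)).mean()
    return float(
        (2 * mu_r * mu_t + c1) * (2 * cov + c2) / ((mu_r**2 + mu_t**2 + c1) * (var_r + var_t + c2))
    )


def ncc(ref, test, mask=None) -> float:
    """Normalized cross-correlation: mean[(x-mu_x)(y-mu_y)] / (sd_x sd_y)."""
    r, t = _masked(ref, test, mask)
    sr, st = r.std(), t.std()
    if sr == 0 or st == 0:
        raise ValueError("NCC undefined for constant input")
    return float(((r - r.mean()) * (t - t.mean())).mean() / (sr * st))


def snu(vol, roi_list: Sequence[tuple[slice, ...] | tuple]) -> float:
    """Spatial nonuniformity: spread (max - min) of per-ROI mean BMD.

    ROIs are rectangular, given either as tuples of slices or as
    (z0, z1, r0, r1, c0, c1) index bounds.
    """
    arr = np.asarray(getattr(vol, "data", vol), dtype=np.float64)
    if len(roi_list) < 2:
        raise ValueError("SNU needs at least two ROIs")
    means = []
    for roi in roi_list:
        if len(roi) == 6:
            z0, z1, r0, r1, c0, c1 = roi
            sub = arr[z0:z1, r0:r1, c0:c1]
        else:
            sub = arr[tuple(roi)]
        if sub.size == 0:
            raise ValueError("ROI outside the grid or empty")
        means.append(float(sub.mean()))
    return float(abs(max(means) - min(means)))


def linearity_slope(ref, test, mask=None) -> tuple[float, float, float]:
    """OLS of test (y) on reference (x) intensities: (slope, intercept, r^2)."""
    r, t = _masked(ref, test, mask)
    if r.std() == 0:
        raise ValueError("reference is constant; slope undefined")
    res = stats.linregress(r, t)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclasses.dataclass
class BlandAltmanResult:
    """Bias (mean of test-ref) and 95% limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(ref, test, mask=None) -> BlandAltmanResult:
    """Bias and bias +/- 1.96 SD of the voxelwise differences."""
    r, t = _masked(ref, test, mask)
    diff = t - r
    bias = float(diff.mean())
    sd = float(diff.std())
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, diff.size)


@dataclasses.dataclass
class ArchProfile:
    """Intensities sampled along the dental arch plus their agreement."""

    arc_positions: np.ndarray
    ref_values: np.ndarray
    test_values: np.ndarray
    pearson_r: float


def _sample_polyline(slice2d: np.ndarray, polyline: np.ndarray, n_samples: int) -> np.ndarray:
    """Bilinear samples at equal arc-length steps along the polyline."""
    from scipy.ndimage import map_coordinates

    pts = np.asarray(polyline, dtype=np.float64)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    if s[-1] <= 0:
        raise ValueError("degenerate polyline")
    targets = np.linspace(0.0, s[-1], n_samples)
    rows = np.interp(targets, s, pts[:, 0])
    cols = np.interp(targets, s, pts[:, 1])
    return map_coordinates(slice2d, np.vstack([rows, cols]), order=1, mode="nearest")


def arch_profile_correlation(
    ref_slice: np.ndarray,
    test_slice: np.ndarray,
    polyline: np.ndarray,
    n_samples: int = 200,
) -> ArchProfile:
    """Sample both slices along the same arch polyline and correlate."""
    ref_slice = np.asarray(ref_slice, dtype=np.float64)
    test_slice = np.asarray(test_slice, dtype=np.float64)
    if ref_slice.shape != test_slice.shape:
        raise ValueError("slices must be congruent")
    rv = _sample_polyline(ref_slice, polyline, n_samples)
    tv = _sample_polyline(test_slice, polyline, n_samples)
    r = float(stats.pearsonr(rv, tv).statistic)
    arc = np.linspace(0.0, 1.0, n_samples)
    return ArchProfile(arc, rv, tv, r)


def percent_improvement(qcbct_value: float, other_value: float, direction: str) -> float:
    """Relative gain of the hybrid network over a comparator, percent.

    lower_better -> 100*(other - qcbct)/other (e.g. MAD, SNU);
    higher_better -> 100*(qcbct - other)/other (e.g. PSNR, SSIM, NCC, slope).
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"bad direction {direction!r}")
    if other_value == 0:
        raise ValueError("comparator value is zero")
    if direction == "lower_better":
        return 100.0 * (other_value - qcbct_value) / other_value
    return 100.0 * (qcbct_value - other_value) / other_value


def paired_ttest(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test on per-slice metric values."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length samples of size >= 2")
    if np.std(a - b) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def region_aggregate(
    per_slice_values: Sequence[float],
    region_map: Optional[Sequence[str]] = None,
) -> dict[str, tuple[float, float]]:
    """Mean +/- SD of a per-slice metric within each anatomical region.

    ``region_map`` labels every slice; by default the first 81 of 200
    slices are maxilla and the rest mandible (scaled proportionally for
    other slice counts).
    """
    vals = np.asarray(per_slice_values, dtype=np.float64)
    n = vals.size
    if region_map is None:
        n_max = int(round(n * 81 / 200)) or 1
        region_map = ["maxilla"] * n_max + ["mandible"] * (n - n_max)
    region_map = list(region_map)
    if len(region_map) != n:
        raise ValueError("region_map must label every slice")
    out: dict[str, tuple[float, float]] = {}
    for region in dict.fromkeys(region_map):
        sel = vals[[r == region for r in region_map]]
        if sel.size == 0:
            raise ValueError(f"empty region {region!r}")
        out[region] = (float(sel.mean()), float(sel.std()))
    return out


def compare_reports(report_a: dict, report_b: dict) -> dict[str, tuple[float, float]]:
    """Paired two-tailed t-tests between two methods' per-slice metrics.

    Both reports must come from :func:`metric_report` over the same slices;
    returns {metric: (t, p)}. The customary significance level for these
    comparisons is 0.01.
    """
    out: dict[str, tuple[float, float]] = {}
    a_rows = {r["slice"]: r for r in report_a["per_slice"]}
    b_rows = {r["slice"]: r for r in report_b["per_slice"]}
    common = sorted(set(a_rows) & set(b_rows))
    if len(common) < 2:
        raise ValueError("need at least two common slices")
    for metric in ("mad", "psnr", "ssim", "ncc", "slope"):
        va = np.array([a_rows[k][metric] for k in common], dtype=float)
        vb = np.array([b_rows[k][metric] for k in common], dtype=float)
        keep = np.isfinite(va) & np.isfinite(vb)
        if keep.sum() >= 2 and np.std(va[keep] - vb[keep]) > 0:
            out[metric] = paired_ttest(va[keep], vb[keep])
    return out


def metric_report(
    ref_vol,
    test_vol,
    mask=None,
    max_intensity: float = DEFAULT_DYNAMIC_RANGE,
    region_map: Optional[Sequence[str]] = None,
) -> dict:
    """Per-slice MAD/PSNR/SSIM/NCC and region means for a volume pair.

    Slices whose mask is empty (or constant, for NCC) are skipped in the
    per-slice lists; the region aggregation follows the kept slices.
    """
    ref = np.asarray(getattr(ref_vol, "data", ref_vol), dtype=np.float64)
    test = np.asarray(getattr(test_vol, "data", test_vol), dtype=np.float64)
    if mask is None:
        m = (ref != BACKGROUND_SENTINEL) & (test != BACKGROUND_SENTINEL)
    else:
        m = np.asarray(getattr(mask, "data", mask)).astype(bool)
    rows = []
    regions_kept = []
    n = ref.shape[0]
    if region_map is None:
        n_max = int(round(n * 81 / 200)) or 1
        region_map = ["maxilla"] * n_max + ["mandible"] * (n - n_max)
    for k in range(n):
        mk = m[k]
        if not mk.any():
            continue
        rk, tk = ref[k], test[k]
        row = {
            "slice": k,
            "region": region_map[k],
            "mad": mad(rk, tk, mk),
            "psnr": psnr(rk, tk, mk, max_intensity),
            "ssim": ssim(rk, tk, mk, dynamic_range=max_intensity),
        }
        try:
            row["ncc"] = ncc(rk, tk, mk)
        except ValueError:
            row["ncc"] = float("nan")
        try:
            row["slope"] = linearity_slope(rk, tk, mk)[0]
        except ValueError:
            row["slope"] = float("nan")
        rows.append(row)
        regions_kept.append(region_map[k])
    report = {"per_slice": rows, "regions": {}}
    for metric in ("mad", "psnr", "ssim", "ncc", "slope"):
        vals = [r[metric] for r in rows if np.isfinite(r[metric])]
        regs = [r["region"] for r in rows if np.isfinite(r[metric])]
        if vals:
            report["regions"][metric] = region_aggregate(vals, regs)
    return report
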