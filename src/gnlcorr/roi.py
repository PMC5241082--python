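"""ROI histogram statistics and correction-efficiency metrics.

The figures of merit for bias correction on a uniform phantom are:

* median and full-width-at-half-maximum (FWHM) of the in-ROI ADC histogram
  (binned 0.02 between 1 and 2.5, in 1e-3 mm^2/s);
* nonuniformity = FWHM / median;
* percent bias = 100 (median - reference) / reference against the
  isocenter reference scan;
* cross-system variability = range / median of a metric across systems;
* exact Wilcoxon rank-sum p-values for pre/post changes and Pearson R for
  metric/parameter dependencies.

FWHM uses the outermost half-maximum crossings of the binned histogram with
linear interpolation between bin centers (robust to the skewed, non-Gaussian
broadening that spatial bias induces), floored at one bin width.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .adc import ADCMap
from .grids import ImageGeometry

HIST_RANGE = (1.0, 2.5)
HIST_STEP = 0.02


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned ROI given by per-axis mm bounds in (AP, RL, SI)."""

    bounds_mm: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    kind: str = "rectangular"

    def __post_init__(self) -> None:
        for lo, hi in self.bounds_mm:
            if not (lo < hi):
                raise ValueError("ROI bounds must be ordered (lo < hi) per axis")
        if self.kind not in ("rectangular", "cubic"):
            raise ValueError("ROI kind must be rectangular or cubic")

    @classmethod
    def cube(cls, center_mm, side_mm: float = 30.0) -> "ROISpec":
        c = np.asarray(center_mm, float)
        h = side_mm / 2.0
        return cls(tuple((float(ci - h), float(ci + h)) for ci in c), kind="cubic")

    @property
    def centroid_mm(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bounds_mm])

    @property
    def volume_cm3(self) -> float:
        v = 1.0
        for lo, hi in self.bounds_mm:
            v *= (hi - lo)
        return v / 1000.0

    def mask(self, geometry: ImageGeometry) -> np.ndarray:
        pts = geometry.voxel_centers_mm()
        m = np.ones(geometry.shape, bool)
        for ax, (lo, hi) in enumerate(self.bounds_mm):
            m &= (pts[..., ax] >= lo) & (pts[..., ax] <= hi)
        return m


@dataclass(frozen=True)
class HistogramStats:
    median: float
    fwhm: float
    n_voxels: int
    bin_edges: np.ndarray = field(repr=False, default=None)

    @property
    def nonuniformity(self) -> float:
        return self.fwhm / self.median


@dataclass
class SystemSummary:
    """Per-system pre/post/reference record of ROI histogram metrics."""

    system: str
    position: int
    pre: HistogramStats
    post: HistogramStats
    reference_median: float
    reference_ci: float

    @property
    def percent_bias_pre(self) -> float:
        return percent_bias(self.pre, self.reference_median)

    @property
    def percent_bias_post(self) -> float:
        return percent_bias(self.post, self.reference_median)


def _fwhm_from_histogram(counts: np.ndarray, centers: np.ndarray, step: float) -> float:
    """Outermost half-maximum crossings, linearly interpolated."""
    cmax = counts.max()
    if cmax <= 0:
        return step
    half = cmax / 2.0
    above = np.flatnonzero(counts >= half)
    i0, i1 = above[0], above[-1]
    if i0 == 0:
        left = centers[0] - step / 2.0
    else:
        frac = (half - counts[i0 - 1]) / (counts[i0] - counts[i0 - 1])
        left = centers[i0 - 1] + frac * step
    if i1 == len(counts) - 1:
        right = centers[-1] + step / 2.0
    else:
        frac = (counts[i1] - half) / (counts[i1] - counts[i1 + 1])
        right = centers[i1] + frac * step
    return max(right - left, step)


def histogram_stats(
    values: np.ndarray,
    bin_step: float = HIST_STEP,
    value_range: tuple[float, float] = HIST_RANGE,
    smooth_window: int = 1,
) -> HistogramStats:
    """Median (of the raw values) and histogram FWHM of a sample.

    The median is taken on the raw sample, independent of binning.  An odd
    ``smooth_window`` > 1 applies a moving-average smoothing to the counts
    before the half-maximum search (off by default).
    """
    v = np.asarray(values, float).ravel()
    edges = np.arange(value_range[0], value_range[1] + bin_step / 2, bin_step)
    counts, _ = np.histogram(v, bins=edges)
    counts = counts.astype(float)
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        kern = np.ones(smooth_window) / smooth_window
        counts = np.convolve(counts, kern, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    fwhm = _fwhm_from_histogram(counts, centers, bin_step)
    return HistogramStats(float(np.median(v)), float(fwhm), len(v), edges)


def roi_histogram(
    adc: ADCMap,
    roi: ROISpec,
    bin_step: float = HIST_STEP,
    value_range: tuple[float, float] = HIST_RANGE,
    min_voxels: int = 50,
    smooth_window: int = 1,
) -> HistogramStats:
    """Histogram statistics of valid ADC voxels inside an ROI."""
    m = roi.mask(adc.geometry)
    if not m.any():
        raise ValueError("ROI does not intersect the image volume")
    vals = adc.values[m & adc.mask]
    if len(vals) < min_voxels:
        raise ValueError(
            f"only {len(vals)} valid voxels in ROI (need >= {min_voxels})"
        )
    return histogram_stats(vals, bin_step, value_range, smooth_window)


def percent_bias(stats_or_median, ref_median: float) -> float:
    """Percent deviation of the ROI median from the reference value."""
    if ref_median <= 0:
        raise ValueError("reference median must be positive")
    med = getattr(stats_or_median, "median", stats_or_median)
    return 100.0 * (med - ref_median) / ref_median


def cross_system_summary(values: list[float] | np.ndarray) -> dict[str, float]:
    """Median, range and range-to-median ratio of a metric across systems."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least two systems")
    med = float(np.median(v))
    rng = float(v.max() - v.min())
    return {"median": med, "range": rng, "range_to_median": rng / med}


def rank_sum_exact(
    x,
    y,
    enumeration_limit: int = 24,
    fallback_normal: bool = False,
) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value by complete enumeration.

    Enumerates all C(n+m, n) group assignments of the midranked pooled
    sample (so ties are handled exactly) and doubles the smaller tail of
    the rank-sum statistic, capped at 1.  Beyond ``enumeration_limit``
    pooled observations the enumeration is refused unless
    ``fallback_normal`` requests the normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    if n + m > enumeration_limit:
        if not fallback_normal:
            raise ValueError(
                f"pooled sample size {n + m} exceeds the exact enumeration "
                f"limit {enumeration_limit}; pass fallback_normal=True for "
                "the normal approximation"
            )
        return float(stats.ranksums(x, y).pvalue)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n].sum()
    lo = hi = 0
    total = math.comb(n + m, n)
    for idx in itertools.combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson R with the two-sided t-transform p-value (n-2 dof)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("samples must be equal-length 1D with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("samples must have nonzero variance")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def reference_roi_measure(adc: ADCMap, side_mm: float = 30.0) -> dict[str, float]:
    """Isocenter cubic-ROI reference statistics.

    The confidence interval is reported as 2 SD — for the noise-dominated
    (Gaussian) reference region the histogram FWHM is equivalent to the
    mean +/- 2 SD (95% CI) description.
    """
    roi = ROISpec.cube((0.0, 0.0, 0.0), side_mm)
    m = roi.mask(adc.geometry)
    if not m.any():
        raise ValueError("isocenter is not inside the image volume")
    vals = adc.values[m & adc.mask]
    if len(vals) == 0:
        raise ValueError("no valid voxels in the reference ROI")
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "median": float(np.median(vals)),
        "ci": 2.0 * (float(vals.std(ddof=1)) if len(vals) > 1 else 0.0),
        "n_voxels": int(len(vals)),
        "volume_cm3": roi.volume_cm3,
    }


def percentile_summary(values, percentiles=(5, 25, 50, 75, 95)) -> dict[int, float]:
    """Box-plot-style percentile summary of a sample (e.g. percent-bias maps)."""
    v = np.asarray(values, float)
    return {int(p): float(np.percentile(v, p)) for p in percentiles}
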