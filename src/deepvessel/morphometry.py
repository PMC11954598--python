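"""3D voxel-wise vascular morphometry.

From a binary vessel segmentation three co-registered voxel sets are
derived: the vessel volume ``A``, its topology-preserving 3D skeleton ``S``
and its surface ``P`` (vessel voxels with at least one 6-connected neighbor
outside the vessel; the volume border counts as outside).  Five metrics are
then evaluated in sliding cubic windows of side ``n``:

* VVD — vessel volume density, ``sum(A) / n^3``
* VTI — vessel thickness index, ``sum(A) / sum(S)`` (a diameter proxy)
* VSD — vessel skeleton density, ``sum(S) / n^3`` (network density)
* VCI — vessel complexity index, ``sum(P)^2 / (4 pi sum(A))`` (morphological
  irregularity)
* VSI — vessel surface-area index, ``sum(P) / n^3`` (exchange surface)

Windows without vessel (or skeleton) voxels leave the affected metrics
undefined — flagged, never imputed as zero — and are excluded from depth
profiles, dispersion statistics, correlations and classifier features.

Segmentation is automatic Otsu thresholding with two reconstructed
variants: proportion-adjusted (threshold shifted until the foreground
fraction enters a plausible vessel-fraction band) and weighted-optimal
(exhaustive threshold sweep scoring between-class separation together with
a foreground-fraction prior).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _skimage_skeletonize

from .core import ImageStack, MaskVolume

logger = logging.getLogger("deepvessel")

__all__ = [
    "LabelVolumes",
    "MetricMaps",
    "DispersionStats",
    "METRIC_NAMES",
    "otsu_segment",
    "skeletonize",
    "surface_extract",
    "build_label_volumes",
    "window_metrics",
    "depth_profiles",
    "dispersion",
    "metric_correlation",
    "region_stats",
]

METRIC_NAMES = ("VVD", "VTI", "VSD", "VCI", "VSI")


@dataclass
class LabelVolumes:
    """Co-registered vessel volume A, skeleton S and surface P."""

    A: np.ndarray
    S: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=bool)
        self.S = np.asarray(self.S, dtype=bool)
        self.P = np.asarray(self.P, dtype=bool)
        if not (self.A.shape == self.S.shape == self.P.shape):
            raise ValueError("A, S, P must be co-registered")
        if np.any(self.S & ~self.A):
            raise ValueError("skeleton voxels must be vessel voxels (S ⊆ A)")
        if np.any(self.P & ~self.A):
            raise ValueError("surface voxels must be vessel voxels (P ⊆ A)")


@dataclass
class MetricMaps:
    """Window-grid maps of the five metrics plus defined-ness flags.

    ``values[name]`` has shape ``grid_shape``; ``defined[name]`` is False
    where the metric's denominator vanished (value is NaN there).
    ``origins`` are the (z, y, x) voxel coordinates of each window's start.
    """

    values: dict[str, np.ndarray]
    defined: dict[str, np.ndarray]
    window: int
    stride: int
    origins: tuple[np.ndarray, np.ndarray, np.ndarray]
    z_step: float = 2.0
    z0_depth: float = 0.0

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.values["VVD"].shape

    def window_depths(self) -> np.ndarray:
        """Depth (µm) of each grid z index, at the window center."""
        return self.z0_depth + (self.origins[0] + self.window / 2) * self.z_step

    def feature_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_windows, 5) feature matrix over fully defined windows.

        Returns the features and the (n_windows, 3) grid indices.
        """
        all_defined = np.ones(self.grid_shape, dtype=bool)
        for name in METRIC_NAMES:
            all_defined &= self.defined[name]
        idx = np.argwhere(all_defined)
        feats = np.stack(
            [self.values[name][all_defined] for name in METRIC_NAMES], axis=1
        )
        return feats, idx


@dataclass
class DispersionStats:
    """CV-vs-depth series per metric, with regional MCV and adjacent DMCV."""

    cv: dict[str, np.ndarray]
    depths: np.ndarray
    mcv: dict[str, dict[int, float]]
    dmcv: dict[str, dict[tuple[int, int], float]]
    region_of_bin: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# segmentation


def _otsu_threshold(values: np.ndarray) -> float:
    return float(threshold_otsu(values))


def otsu_segment(
    image: ImageStack | np.ndarray,
    method: str = "global_otsu",
    per_frame: bool = False,
    fraction_band: tuple[float, float] = (0.01, 0.20),
    prior_weight: float = 1.0,
    n_sweep: int = 256,
) -> MaskVolume:
    """Threshold-based vessel segmentation.

    ``global_otsu`` maximizes the between-class variance of the intensity
    histogram.  ``proportion_adjusted`` starts from the Otsu threshold and
    shifts it until the foreground fraction lies inside ``fraction_band``.
    ``weighted_optimal`` sweeps ``n_sweep`` candidate thresholds and
    maximizes normalized between-class variance minus ``prior_weight`` times
    a squared penalty on the distance of the foreground fraction from the
    band.  A constant image yields an empty mask with a warning.
    """
    voxels = image.voxels if isinstance(image, ImageStack) else np.asarray(image, float)
    if voxels.ndim == 2:
        voxels = voxels[None]
    if not np.all(np.isfinite(voxels)):
        raise ValueError("intensities must be finite")
    if per_frame:
        frames = [
            otsu_segment(voxels[k], method, False, fraction_band, prior_weight, n_sweep).voxels[0]
            for k in range(voxels.shape[0])
        ]
        return MaskVolume(np.stack(frames), role="vessel_truth")

    flat = voxels.ravel()
    if flat.max() == flat.min():
        warnings.warn("constant image: no threshold exists; returning empty mask", RuntimeWarning)
        return MaskVolume(np.zeros_like(voxels, dtype=bool), role="vessel_truth")

    if method == "global_otsu":
        thr = _otsu_threshold(flat)
    elif method == "proportion_adjusted":
        thr = _otsu_threshold(flat)
        frac = float(np.mean(flat > thr))
        lo_band, hi_band = fraction_band
        if frac > hi_band:
            thr = float(np.quantile(flat, 1 - hi_band))
        elif frac < lo_band:
            thr = float(np.quantile(flat, 1 - lo_band))
    elif method == "weighted_optimal":
        lo_band, hi_band = fraction_band
        candidates = np.quantile(flat, np.linspace(0.005, 0.995, n_sweep))
        candidates = np.unique(candidates)
        best_score, thr = -np.inf, candidates[0]
        total_var = flat.var()
        for c in candidates:
            fg = flat > c
            w1 = fg.mean()
            if w1 in (0.0, 1.0):
                continue
            w0 = 1 - w1
            mu1, mu0 = flat[fg].mean(), flat[~fg].mean()
            bcv = w0 * w1 * (mu1 - mu0) ** 2 / total_var
            if w1 < lo_band:
                penalty = (lo_band - w1) ** 2
            elif w1 > hi_band:
                penalty = (w1 - hi_band) ** 2
            else:
                penalty = 0.0
            score = bcv - prior_weight * penalty
            if score > best_score:
                best_score, thr = score, float(c)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    mask = voxels > thr
    logger.info("otsu_segment[%s]: threshold=%.4g foreground=%.3f", method, thr, mask.mean())
    return MaskVolume(mask, role="vessel_truth")


# ---------------------------------------------------------------------------
# label volumes


def skeletonize(A: np.ndarray | MaskVolume) -> np.ndarray:
    """Topology-preserving 3D medial-axis thinning (Lee-type)."""
    a = A.voxels if isinstance(A, MaskVolume) else np.asarray(A, dtype=bool)
    if not a.any():
        return np.zeros_like(a)
    return _skimage_skeletonize(a).astype(bool)


def surface_extract(A: np.ndarray | MaskVolume, connectivity: int = 1) -> np.ndarray:
    """Vessel voxels with >= 1 face-neighbor outside the vessel volume.

    ``connectivity=1`` uses 6-connected face adjacency (default);
    ``connectivity=3`` uses the full 26-neighborhood.  The volume border
    counts as outside.
    """
    a = A.voxels if isinstance(A, MaskVolume) else np.asarray(A, dtype=bool)
    struct = ndimage.generate_binary_structure(3, connectivity)
    eroded = ndimage.binary_erosion(a, structure=struct, border_value=0)
    return a & ~eroded


def build_label_volumes(A: np.ndarray | MaskVolume, connectivity: int = 1) -> LabelVolumes:
    a = A.voxels if isinstance(A, MaskVolume) else np.asarray(A, dtype=bool)
    return LabelVolumes(A=a, S=skeletonize(a), P=surface_extract(a, connectivity))


# ---------------------------------------------------------------------------
# windowed metrics


def _window_sums(vol: np.ndarray, n: int, stride: int) -> np.ndarray:
    """Sums of all n-cubes on the stride grid, via a 3D summed-area table."""
    c = np.zeros(tuple(s + 1 for s in vol.shape), dtype=np.float64)
    c[1:, 1:, 1:] = vol.astype(np.float64).cumsum(0).cumsum(1).cumsum(2)
    starts = [np.arange(0, s - n + 1, stride) for s in vol.shape]
    z0, y0, x0 = np.meshgrid(*starts, indexing="ij")
    z1, y1, x1 = z0 + n, y0 + n, x0 + n
    return (
        c[z1, y1, x1]
        - c[z0, y1, x1]
        - c[z1, y0, x1]
        - c[z1, y1, x0]
        + c[z0, y0, x1]
        + c[z0, y1, x0]
        + c[z1, y0, x0]
        - c[z0, y0, x0]
    )


def window_metrics(
    labels: LabelVolumes,
    window: int = 32,
    stride: int | None = None,
    z_step: float = 2.0,
    z0_depth: float = 0.0,
) -> MetricMaps:
    """Evaluate the five metrics in sliding cubic windows.

    Windows are anchored on a regular grid with the given stride (default
    ``window // 2``).  VTI and VCI are undefined (NaN, flagged) in windows
    whose skeleton or vessel sums vanish.
    """
    if stride is None:
        stride = max(window // 2, 1)
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be positive integers")
    if window > min(labels.A.shape):
        raise ValueError(f"window {window} exceeds volume shape {labels.A.shape}")

    sum_A = _window_sums(labels.A, window, stride)
    sum_S = _window_sums(labels.S, window, stride)
    sum_P = _window_sums(labels.P, window, stride)
    n3 = float(window**3)

    with np.errstate(divide="ignore", invalid="ignore"):
        vvd = sum_A / n3
        vti = np.where(sum_S > 0, sum_A / np.maximum(sum_S, 1), np.nan)
        vsd = sum_S / n3
        vci = np.where(sum_A > 0, sum_P**2 / (4 * np.pi * np.maximum(sum_A, 1)), np.nan)
        vsi = sum_P / n3

    values = {"VVD": vvd, "VTI": vti, "VSD": vsd, "VCI": vci, "VSI": vsi}
    always = np.ones_like(sum_A, dtype=bool)
    defined = {
        "VVD": always,
        "VTI": sum_S > 0,
        "VSD": always,
        "VCI": sum_A > 0,
        "VSI": always,
    }
    starts = tuple(np.arange(0, s - window + 1, stride) for s in labels.A.shape)
    return MetricMaps(
        values=values,
        defined=defined,
        window=window,
        stride=stride,
        origins=starts,
        z_step=z_step,
        z0_depth=z0_depth,
    )


def upsample_map(maps: MetricMaps, name: str, shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbor upsampling of a grid map to full voxel resolution."""
    grid = maps.values[name]
    out = np.full(shape, np.nan)
    zs, ys, xs = maps.origins
    for i, z in enumerate(zs):
        for j, y in enumerate(ys):
            for k, x in enumerate(xs):
                out[z : z + maps.stride, y : y + maps.stride, x : x + maps.stride] = grid[i, j, k]
    return out


# ---------------------------------------------------------------------------
# profiles, dispersion, correlation, region statistics


def depth_profiles(
    maps: MetricMaps, n_hist_bins: int = 20
) -> dict[str, dict[str, np.ndarray]]:
    """Per-metric depth profile (mean over defined windows per grid z) and histogram.

    Depth bins with no defined window appear as NaN gaps, not zeros.
    """
    depths = maps.window_depths()
    out: dict[str, dict[str, np.ndarray]] = {}
    for name in METRIC_NAMES:
        v, d = maps.values[name], maps.defined[name]
        means = np.full(v.shape[0], np.nan)
        for i in range(v.shape[0]):
            if d[i].any():
                means[i] = v[i][d[i]].mean()
        vals = v[d]
        if vals.size:
            hist, edges = np.histogram(vals, bins=n_hist_bins)
        else:
            hist, edges = np.zeros(n_hist_bins, dtype=int), np.linspace(0, 1, n_hist_bins + 1)
        out[name] = {"depth": depths, "mean": means, "hist": hist, "hist_edges": edges}
    return out


def dispersion(maps: MetricMaps, region_of_bin: np.ndarray) -> DispersionStats:
    """Coefficient-of-variation statistics across depth.

    ``region_of_bin`` assigns a region label to every grid z bin.  Per metric
    and bin, CV = std/mean over that bin's defined windows (NaN for a zero
    mean); MCV is the mean CV over a region's bins; DMCV is the absolute MCV
    difference between adjacent regions in label order.
    """
    region_of_bin = np.asarray(region_of_bin)
    nz = maps.grid_shape[0]
    if len(region_of_bin) != nz:
        raise ValueError(f"need one region label per grid z bin ({nz})")
    depths = maps.window_depths()
    cv: dict[str, np.ndarray] = {}
    mcv: dict[str, dict[int, float]] = {}
    dmcv: dict[str, dict[tuple[int, int], float]] = {}
    region_ids = [int(r) for r in np.unique(region_of_bin)]
    for name in METRIC_NAMES:
        v, d = maps.values[name], maps.defined[name]
        series = np.full(nz, np.nan)
        for i in range(nz):
            vals = v[i][d[i]]
            if vals.size >= 2 and vals.mean() != 0:
                series[i] = vals.std() / vals.mean()
            elif vals.size >= 2:
                series[i] = np.nan
        cv[name] = series
        mcv[name] = {}
        for rid in region_ids:
            sel = (region_of_bin == rid) & np.isfinite(series)
            mcv[name][rid] = float(series[sel].mean()) if sel.any() else float("nan")
        dmcv[name] = {}
        for r1, r2 in zip(region_ids[:-1], region_ids[1:]):
            dmcv[name][(r1, r2)] = abs(mcv[name][r1] - mcv[name][r2])
    return DispersionStats(cv=cv, depths=depths, mcv=mcv, dmcv=dmcv, region_of_bin=region_of_bin)


def metric_correlation(
    maps: MetricMaps, threshold: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation among the five metrics over co-defined windows.

    Returns the 5x5 matrix and a boolean flag matrix marking pairs with
    ``|r| >= threshold`` as non-independent (the screen keeps metrics whose
    absolute pairwise correlation stays below 0.7).
    """
    all_defined = np.ones(maps.grid_shape, dtype=bool)
    for name in METRIC_NAMES:
        all_defined &= maps.defined[name]
    n = int(all_defined.sum())
    if n < 3:
        raise ValueError(f"need >= 3 co-defined windows, have {n}")
    X = np.stack([maps.values[name][all_defined] for name in METRIC_NAMES])
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X)
    flags = np.abs(r) >= threshold
    return r, flags


def region_stats(
    samples: dict[int, np.ndarray] | dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict:
    """Per-region summaries and group comparisons for one metric.

    ``samples`` maps region label -> 1D array of window values.  Returns
    per-region mean/sd, min–max normalized means (radar-chart convention),
    and a two-sided Welch t-test for 2 groups or one-way ANOVA with Tukey
    HSD pairwise p-values for >= 3 groups.  Degenerate groups (fewer than 2
    samples) skip the tests with a warning.
    """
    keys = list(samples)
    groups = [np.asarray(samples[k], dtype=float) for k in keys]
    if len(groups) < 2:
        raise ValueError("need >= 2 regions")
    out: dict = {"regions": {}, "alpha": alpha}
    means = []
    for k, g in zip(keys, groups):
        out["regions"][k] = {
            "n": int(g.size),
            "mean": float(g.mean()) if g.size else float("nan"),
            "sd": float(g.std(ddof=1)) if g.size > 1 else float("nan"),
        }
        means.append(out["regions"][k]["mean"])
    lo, hi = min(means), max(means)
    for k, m in zip(keys, means):
        out["regions"][k]["normalized_mean"] = (m - lo) / (hi - lo) if hi > lo else 0.0

    if any(g.size < 2 for g in groups):
        warnings.warn("degenerate group (<2 samples); significance tests skipped", RuntimeWarning)
        return out

    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        out["test"] = {"kind": "welch_t", "statistic": float(t), "p_value": float(p)}
    else:
        F, p = stats.f_oneway(*groups)
        out["test"] = {"kind": "anova", "statistic": float(F), "p_value": float(p)}
        tk = stats.tukey_hsd(*groups)
        out["tukey"] = {
            f"{keys[i]}-{keys[j]}": float(tk.pvalue[i, j])
            for i in range(len(keys))
            for j in range(i + 1, len(keys))
        }
    return out
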