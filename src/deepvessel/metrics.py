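"""Image-quality and segmentation-accuracy metrics.

Implements the evaluation suite used throughout the pipeline:

* SBR — signal-to-background ratio, the mean intensity over an annotated
  signal region divided by the mean over an annotated background region, plus
  depth-binned SBR profiles for z-stacks.
* SSIM — structural similarity, scored per sliding window as
  ``(2 mu_u mu_v + Q1)(2 cov_uv + Q2) / ((mu_u^2 + mu_v^2 + Q1)(var_u + var_v + Q2))``
  with small positive constants Q1, Q2 (default 0.01) and averaged over
  windows.  A compatibility flag switches to the classic formulation in which
  the constants scale with the squared dynamic range.
* MSE / PSNR — mean squared error and ``10 log10(max(I)^2 / MSE)``.
* F1 — harmonic mean of sensitivity and precision over voxel-wise confusion
  counts, ``2 TP / (2 TP + FP + FN)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageStack, MaskVolume

__all__ = [
    "MetricConfig",
    "ConfusionCounts",
    "sbr",
    "sbr_depth_profile",
    "mse",
    "psnr",
    "ssim",
    "confusion",
    "f1",
    "background_mask_from_truth",
]


@dataclass
class MetricConfig:
    """SSIM constants and windowing.

    ``q1``/``q2`` are the small positive stabilizers added to the luminance
    and contrast terms.  With ``classic_scaling`` they are interpreted as
    K1/K2 of the classic formulation and become ``(K * dynamic_range)**2``;
    otherwise they are used exactly as given.
    """

    q1: float = 0.01
    q2: float = 0.01
    window: int = 11
    dynamic_range: float = 1.0
    classic_scaling: bool = False
    sample_covariance: bool = False

    def __post_init__(self) -> None:
        if self.q1 <= 0 or self.q2 <= 0:
            raise ValueError("Q1 and Q2 must be positive")
        if self.window < 2:
            raise ValueError("SSIM window must be >= 2 pixels")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageStack):
        return image.voxels
    return np.asarray(image, dtype=np.float64)


def _as_mask(mask) -> np.ndarray:
    if isinstance(mask, MaskVolume):
        return mask.voxels
    return np.asarray(mask, dtype=bool)


def sbr(image, signal_mask, background_mask) -> float:
    """Signal-to-background ratio: mean(signal) / mean(background).

    Returns ``inf`` (with a warning) when the background mean is zero.
    """
    img = _as_array(image)
    sig = _as_mask(signal_mask)
    bg = _as_mask(background_mask)
    if sig.shape != img.shape or bg.shape != img.shape:
        raise ValueError("masks must be co-registered with the image")
    if not sig.any() or not bg.any():
        raise ValueError("signal and background masks must each be non-empty")
    if np.logical_and(sig, bg).any():
        raise ValueError("signal and background masks must be disjoint")
    mu_bg = float(img[bg].mean())
    mu_sig = float(img[sig].mean())
    if mu_bg == 0.0:
        warnings.warn("background mean is zero; SBR is infinite", RuntimeWarning)
        return float("inf")
    return mu_sig / mu_bg


def sbr_depth_profile(
    stack: ImageStack,
    signal_mask,
    background_mask,
    bin_frames: int = 1,
) -> list[tuple[float, float]]:
    """SBR per depth bin, using intensities pooled over ``bin_frames`` frames.

    Returns ``(depth_um, SBR)`` pairs; the depth is the mean frame depth of
    the bin.  Bins in which either mask is empty are skipped.
    """
    if bin_frames < 1:
        raise ValueError("bin_frames must be >= 1")
    img = stack.voxels
    sig = _as_mask(signal_mask)
    bg = _as_mask(background_mask)
    if sig.shape != img.shape or bg.shape != img.shape:
        raise ValueError("masks must be co-registered with the stack")
    depths = stack.depths()
    profile: list[tuple[float, float]] = []
    for start in range(0, stack.n_frames, bin_frames):
        sl = slice(start, min(start + bin_frames, stack.n_frames))
        if not (sig[sl].any() and bg[sl].any()):
            continue
        profile.append((float(depths[sl].mean()), sbr(img[sl], sig[sl], bg[sl])))
    return profile


def mse(test, reference) -> float:
    """Mean squared error over all pixels."""
    t = _as_array(test)
    r = _as_array(reference)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    return float(np.mean((t - r) ** 2))


def psnr(test, reference, max_val: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(max(I)^2 / MSE)``.

    ``max_val`` defaults to the maximum of the reference; identical inputs
    yield ``inf``.
    """
    err = mse(test, reference)
    if max_val is None:
        max_val = float(_as_array(reference).max())
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    if err == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_val**2 / err)


def ssim(test, reference, cfg: MetricConfig | None = None) -> float:
    """Mean windowed structural similarity between two images.

    Local means/variances/covariance are computed in sliding uniform windows
    (2D per frame; a 3D stack is scored frame-wise and averaged); each window
    is scored by the similarity formula and the border region in which the
    window extends past the image is cropped before averaging.
    """
    cfg = cfg or MetricConfig()
    t = _as_array(test)
    r = _as_array(reference)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    if t.ndim == 3:
        return float(np.mean([ssim(t[k], r[k], cfg) for k in range(t.shape[0])]))
    if t.ndim != 2:
        raise ValueError("ssim expects 2D frames or 3D stacks")
    win = cfg.window
    if win > min(t.shape):
        raise ValueError(f"SSIM window {win} larger than image {t.shape}")

    if cfg.classic_scaling:
        c1 = (cfg.q1 * cfg.dynamic_range) ** 2
        c2 = (cfg.q2 * cfg.dynamic_range) ** 2
    else:
        c1, c2 = cfg.q1, cfg.q2

    filt = lambda a: ndimage.uniform_filter(a, size=win)
    ux, uy = filt(t), filt(r)
    uxx, uyy, uxy = filt(t * t), filt(r * r), filt(t * r)
    if cfg.sample_covariance:
        np_ = win**2
        norm = np_ / (np_ - 1)
    else:
        norm = 1.0
    vx = norm * (uxx - ux * ux)
    vy = norm * (uyy - uy * uy)
    vxy = norm * (uxy - ux * uy)

    score = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    return float(score[pad:-pad or None, pad:-pad or None].mean())


def confusion(pred, truth) -> ConfusionCounts:
    """Voxel-wise confusion counts of a predicted mask against ground truth."""
    p = _as_mask(pred)
    g = _as_mask(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def f1(counts: ConfusionCounts) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); empty-vs-empty agreement scores 1."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        warnings.warn("no positives in prediction or truth; F1 defined as 1.0", RuntimeWarning)
        return 1.0
    return 2 * counts.TP / denom


def background_mask_from_truth(truth, margin: int = 3) -> MaskVolume:
    """Background annotation for phantoms: voxels >= ``margin`` voxels from any vessel.

    Mirrors manual background annotation by excluding a dilated halo around
    the true vessel volume.
    """
    g = _as_mask(truth)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        bg = ~g
    else:
        dilated = ndimage.binary_dilation(g, iterations=margin)
        bg = ~dilated
    return MaskVolume(bg, role="background")
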