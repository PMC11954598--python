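"""Low-rank stripe removal for raster-scanned frames.

Detector ripple noise is modulated into line-wise stripes by the raster line
scan: within one frame the stripe field is constant along the fast-scan axis
and varies across lines.  Such a frame has a dominant rank-1 component, so
its largest singular value stands well above the rest.  The denoiser gates on
the ratio of the two largest singular values sigma1/sigma2 of each 2D frame
(threshold 3 by default); gated frames are rebuilt from a modified spectrum
in which the top singular value(s) are replaced by the next one down, which
suppresses the periodic structure while leaving the remaining components
untouched.  Frames below the gate pass through bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack

logger = logging.getLogger("deepvessel")

__all__ = [
    "SingularSpectrum",
    "StripeReport",
    "svd_frame",
    "stripe_ratio",
    "lr_denoise_frame",
    "lr_denoise_stack",
]


@dataclass
class SingularSpectrum:
    """SVD triple ``X = U diag(S) V^T`` of one 2D frame.

    ``U`` has orthonormal columns (eigenvectors of ``X X^T``), ``V`` has
    orthonormal columns (eigenvectors of ``X^T X``), and ``S`` holds the
    singular values sorted non-increasing.  If the frame had fewer rows than
    columns it was transposed first (``transposed`` records this) so that
    M >= N.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    r: int
    transposed: bool = False

    def reconstruct(self) -> np.ndarray:
        """Rebuild the frame (undoing any internal transposition)."""
        X = (self.U * self.S) @ self.V.T
        return X.T if self.transposed else X


@dataclass
class StripeReport:
    """Per-frame record of the stripe gate decision."""

    ratio: float
    gated: bool
    replaced_values: list[tuple[int, float, float]] = field(default_factory=list)


def svd_frame(frame: np.ndarray) -> SingularSpectrum:
    """Full SVD of a 2D frame with the M >= N transposition convention."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D frame, got ndim={frame.ndim}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    transposed = frame.shape[0] < frame.shape[1]
    X = frame.T if transposed else frame
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    return SingularSpectrum(U=U, S=S, V=Vt.T, r=len(S), transposed=transposed)


def stripe_ratio(spec: SingularSpectrum) -> float:
    """Ratio sigma1/sigma2 of the two largest singular values.

    Returns ``inf`` when sigma2 is zero (a pure rank<=1 frame is all
    structure under this model).
    """
    if spec.r < 2:
        raise ValueError("need at least two singular values for the stripe ratio")
    s1, s2 = float(spec.S[0]), float(spec.S[1])
    # values below the numerical-rank tolerance count as zero
    tol = max(spec.U.shape[0], spec.V.shape[0]) * np.finfo(np.float64).eps * s1
    if s2 <= tol:
        return float("inf")
    return s1 / s2


def lr_denoise_frame(
    frame: np.ndarray,
    threshold: float = 3.0,
    n_replace: int = 1,
) -> tuple[np.ndarray, StripeReport]:
    """Gate a frame on its singular-value ratio and rebuild if gated.

    If sigma1/sigma2 >= ``threshold`` (the gate is inclusive), the top
    ``n_replace`` singular values are replaced by sigma_{n_replace+1} and the
    frame is rebuilt from the modified spectrum; otherwise the input is
    returned unchanged.  Replacing sigma1 by sigma2 makes the new top ratio
    exactly 1, so the operation is idempotent; it also never increases the
    Frobenius norm.
    """
    if not threshold > 1:
        raise ValueError("threshold must be > 1")
    if n_replace < 1:
        raise ValueError("n_replace must be >= 1")
    frame = np.asarray(frame, dtype=np.float64)
    spec = svd_frame(frame)
    ratio = stripe_ratio(spec)
    if not ratio >= threshold:
        return frame, StripeReport(ratio=ratio, gated=False)
    k = min(n_replace, spec.r - 1)
    new_val = float(spec.S[k])
    if ratio == float("inf"):
        new_val = 0.0  # pure rank-<=k structure: nothing real to keep
    replaced = [(j, float(spec.S[j]), new_val) for j in range(k)]
    S_new = spec.S.copy()
    S_new[:k] = new_val
    rebuilt = SingularSpectrum(spec.U, S_new, spec.V, spec.r, spec.transposed).reconstruct()
    return rebuilt, StripeReport(ratio=ratio, gated=True, replaced_values=replaced)


def lr_denoise_stack(
    stack: ImageStack,
    threshold: float = 3.0,
    n_replace: int = 1,
) -> tuple[ImageStack, list[StripeReport]]:
    """Apply the stripe denoiser frame-by-frame to a z-stack.

    The gate is evaluated independently per frame.  Rebuilt frames can carry
    small negative excursions; these are floored at 0 so the result remains a
    valid intensity stack (ungated frames are untouched and pass through
    bit-identical).
    """
    out = np.empty_like(stack.voxels)
    reports: list[StripeReport] = []
    for k in range(stack.n_frames):
        denoised, report = lr_denoise_frame(stack.voxels[k], threshold, n_replace)
        if report.gated:
            np.clip(denoised, 0.0, None, out=denoised)
        out[k] = denoised
        reports.append(report)
    n_gated = sum(r.gated for r in reports)
    if n_gated:
        logger.info("lr_denoise_stack: %d/%d frames gated", n_gated, stack.n_frames)
    return ImageStack(out, stack.z_step, stack.z0_depth, stack.source_dtype), reports
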