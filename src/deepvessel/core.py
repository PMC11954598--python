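"""Core data types, TIFF stack I/O, configuration and seeding.

The pipeline's universal currency is :class:`ImageStack`: a 3D fluorescence
volume with axis order ``(z, y, x)``, where ``z`` indexes depth (one raster
frame per physical z position), ``y`` is the line-scan (row) direction and
``x`` is the fast scan direction within a line.  Structured (stripe) noise
from the detector is constant along ``x`` within each line ``y``; this axis
convention is relied on by the low-rank stripe denoiser and the phantom
generator.

All intensities are processed in floating point regardless of the input bit
depth; integer TIFFs are cast on read and may be re-quantized on write.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("deepvessel")

__all__ = [
    "ImageStack",
    "MaskVolume",
    "DiffusionConfig",
    "PipelineConfig",
    "ConfigError",
    "read_stack",
    "write_stack",
    "load_config",
    "spawn_seeds",
]


class ConfigError(ValueError):
    """Raised when a configuration document violates the schema."""


def _validate_voxels(voxels: np.ndarray) -> np.ndarray:
    voxels = np.asarray(voxels, dtype=np.float64)
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) array, got ndim={voxels.ndim}")
    if voxels.shape[0] < 1:
        raise ValueError("stack must contain at least one frame")
    if not np.all(np.isfinite(voxels)):
        raise ValueError("intensities must be finite")
    if np.any(voxels < 0):
        raise ValueError("intensities must be non-negative")
    return voxels


@dataclass
class ImageStack:
    """3D intensity volume with a physical depth axis.

    Parameters
    ----------
    voxels
        Non-negative intensities, axis order ``(z, y, x)``.
    z_step
        Physical depth increment between consecutive frames, in µm.
    z0_depth
        Depth of the first frame, in µm.
    source_dtype
        Dtype of the file the stack was read from, if any.
    """

    voxels: np.ndarray
    z_step: float = 2.0
    z0_depth: float = 0.0
    source_dtype: str | None = None

    def __post_init__(self) -> None:
        self.voxels = _validate_voxels(self.voxels)
        if not self.z_step > 0:
            raise ValueError("z_step must be positive")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def depths(self) -> np.ndarray:
        """Physical depth (µm) of every frame: ``z0 + k * z_step``."""
        return self.z0_depth + self.z_step * np.arange(self.n_frames)

    def normalized(self) -> tuple["ImageStack", tuple[float, float]]:
        """Return a per-stack min–max normalized copy and the (lo, hi) transform."""
        lo = float(self.voxels.min())
        hi = float(self.voxels.max())
        if hi > lo:
            v = (self.voxels - lo) / (hi - lo)
        else:
            v = np.zeros_like(self.voxels)
        return ImageStack(v, self.z_step, self.z0_depth, self.source_dtype), (lo, hi)

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), self.z_step, self.z0_depth, self.source_dtype)


MaskRole = Literal["signal", "background", "vessel_truth"]


@dataclass
class MaskVolume:
    """Boolean volume co-registered with an :class:`ImageStack`."""

    voxels: np.ndarray
    role: MaskRole = "vessel_truth"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def check_registered(self, stack: ImageStack | "MaskVolume") -> None:
        if self.shape != stack.shape:
            raise ValueError(f"mask shape {self.shape} != volume shape {stack.shape}")


@dataclass
class DiffusionConfig:
    """Gaussian diffusion schedule and training hyperparameters.

    ``T`` diffusion steps with a monotone β schedule; the cumulative products
    ᾱ_t = Π_{s≤t}(1 − β_s) are strictly decreasing in t.  Defaults follow the
    standard linear schedule β: 1e-4 → 2e-2.
    """

    T: int = 200
    beta_start: float = 1e-4
    beta_end: float = 2e-2
    epochs: int = 300
    learning_rate: float = 2e-4
    optimizer: str = "adam"
    patch_size: int = 256
    shallow_fraction: float = 0.2
    batch_size: int = 8
    base_channels: int = 16
    channel_mults: tuple[int, int, int, int] = (1, 2, 2, 4)
    augment_flips: bool = True
    augment_rotations: bool = True

    def __post_init__(self) -> None:
        self.channel_mults = tuple(self.channel_mults)
        if len(self.channel_mults) != 4:
            raise ConfigError("diffusion.channel_mults must list 4 resolution levels")
        if self.T < 1:
            raise ConfigError("diffusion.T must be >= 1")
        if self.epochs < 1:
            raise ConfigError("diffusion.epochs must be >= 1")
        if not (0 < self.beta_start <= self.beta_end < 1):
            raise ConfigError("diffusion betas must satisfy 0 < beta_start <= beta_end < 1")
        if not (0 < self.shallow_fraction <= 1):
            raise ConfigError("diffusion.shallow_fraction must be in (0, 1]")
        if self.patch_size < 8 or self.patch_size % 8 != 0:
            raise ConfigError("diffusion.patch_size must be a multiple of 8 and >= 8")

    def betas(self) -> np.ndarray:
        return np.linspace(self.beta_start, self.beta_end, self.T)

    def alpha_bars(self) -> np.ndarray:
        """ᾱ_t for t = 1..T (index 0 is t=1)."""
        return np.cumprod(1.0 - self.betas())


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration with documented defaults."""

    lr_ratio_threshold: float = 3.0
    neighbor_avg_radius: int = 1
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    segmentation_method: str = "global_otsu"
    morphometry_window: int = 32
    morphometry_stride: int = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_ratio_threshold > 1:
            raise ConfigError("lr_ratio_threshold must be > 1")
        if self.neighbor_avg_radius < 0:
            raise ConfigError("neighbor_avg_radius must be >= 0")
        if self.morphometry_window < 1 or self.morphometry_stride < 1:
            raise ConfigError("morphometry window/stride must be positive integers")
        if self.segmentation_method not in ("global_otsu", "proportion_adjusted", "weighted_optimal"):
            raise ConfigError(f"unknown segmentation method {self.segmentation_method!r}")


def read_stack(path: str | Path, z_step: float = 2.0, z0: float = 0.0) -> ImageStack:
    """Read a single- or multi-page TIFF as an :class:`ImageStack`.

    Page order is taken as increasing depth.  Intensities are cast to float64;
    the original bit depth is recorded on the stack.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    src_dtype = str(arr.dtype)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D or 3D TIFF data, got shape {arr.shape}")
    return ImageStack(arr.astype(np.float64), z_step=z_step, z0_depth=z0, source_dtype=src_dtype)


def write_stack(
    stack: ImageStack,
    path: str | Path,
    dtype: Literal["uint8", "uint16", "float32"] = "float32",
) -> Path:
    """Write a stack as a multi-page TIFF.

    Integer dtypes min–max scale to the full range; the scale is recorded in
    the TIFF ImageDescription so the transform is recoverable.  A constant
    stack is written as zeros with the scale flagged ``"constant"``.
    """
    path = Path(path)
    v = stack.voxels
    if dtype == "float32":
        data = v.astype(np.float32)
        meta = {"scale": "identity"}
    elif dtype in ("uint8", "uint16"):
        lo, hi = float(v.min()), float(v.max())
        full = 255 if dtype == "uint8" else 65535
        if hi > lo:
            data = np.round((v - lo) / (hi - lo) * full).astype(dtype)
            meta = {"scale": "minmax", "lo": lo, "hi": hi, "full": full}
        else:
            data = np.zeros_like(v, dtype=dtype)
            meta = {"scale": "constant", "lo": lo}
    else:
        raise ValueError(f"unsupported dtype tag {dtype!r}")
    meta["z_step_um"] = stack.z_step
    meta["z0_um"] = stack.z0_depth
    try:
        tifffile.imwrite(path, data, photometric="minisblack", description=json.dumps(meta))
    except OSError as exc:
        raise OSError(f"cannot write TIFF {path}: {exc}") from exc
    return path


_DIFFUSION_KEYS = {f.name for f in dataclasses.fields(DiffusionConfig)}
_PIPELINE_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON pipeline configuration, filling documented defaults.

    An empty document yields the default configuration (stripe-ratio gate 3,
    diffusion length T=200).  Unknown or invalid keys raise :class:`ConfigError`
    naming the offending key paths.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        doc = loaded
    if overrides:
        doc.update(overrides)

    bad = sorted(set(doc) - _PIPELINE_KEYS)
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(bad)}")
    diff_doc = doc.pop("diffusion", {}) or {}
    if not isinstance(diff_doc, dict):
        raise ConfigError("diffusion: must be a mapping")
    bad = sorted(set(diff_doc) - _DIFFUSION_KEYS)
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join('diffusion.' + k for k in bad)}")
    try:
        diffusion = DiffusionConfig(**diff_doc)
        return PipelineConfig(diffusion=diffusion, **doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds deterministically from ``seed``.

    Children are below 2**31 so they remain portable integer seeds.
    """
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
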