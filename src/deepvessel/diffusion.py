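"""Self-supervised diffusion denoising of z-stacks.

The denoiser is trained without external ground truth: training patches are
drawn only from the *shallow side* of the stack (the frames nearest the
detection objective, which carry the best image quality), and a Gaussian
diffusion process of length ``T`` provides the supervision signal — the
U-Net learns to predict the noise injected by the closed-form forward
marginal

    x_t = sqrt(abar_t) * x0 + sqrt(1 - abar_t) * eps,   eps ~ N(0, I).

At inference a degraded frame is treated as a partially diffused sample
``x_{t_start}`` and run through ancestral sampling down to t=0.  ``t_start``
is chosen per frame from a robust (median absolute deviation) estimate of
the residual noise level, so nearly clean frames pass through almost
unchanged.  Full-stack enhancement composes three stages: low-rank stripe
removal, neighbor-depth averaging, and the per-frame reverse diffusion.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import DiffusionConfig, ImageStack, PipelineConfig, spawn_seeds
from .lr_denoiser import lr_denoise_stack
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.unet import Adam, UNet

logger = logging.getLogger("deepvessel")

__all__ = [
    "DenoiserModel",
    "TrainingError",
    "extract_shallow_subvolumes",
    "augment",
    "forward_diffuse",
    "train",
    "estimate_t_start",
    "reverse_denoise",
    "neighbor_depth_average",
    "lrdm_enhance",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class DenoiserModel:
    """Trained noise-prediction network plus the schedule it was trained under."""

    net: UNet
    config: DiffusionConfig
    loss_history: list[float] = field(default_factory=list)

    def save(self, path) -> None:
        meta = {
            "format": "deepvessel-ddpm/1",
            "config": asdict(self.config),
            "base_channels": self.net.base_channels,
            "channel_mults": list(self.net.channel_mults),
            "loss_history": self.loss_history,
        }
        buf = io.BytesIO()
        np.savez(buf, **self.net.state_dict())
        with open(path, "wb") as fh:
            header = json.dumps(meta).encode()
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "DenoiserModel":
        with open(path, "rb") as fh:
            n = int.from_bytes(fh.read(8), "little")
            meta = json.loads(fh.read(n).decode())
            if meta.get("format") != "deepvessel-ddpm/1":
                raise ValueError(f"{path}: not a deepvessel diffusion checkpoint")
            blob = io.BytesIO(fh.read())
        cfg = DiffusionConfig(**meta["config"])
        net = UNet(meta["base_channels"], tuple(meta["channel_mults"]))
        with np.load(blob) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return cls(net=net, config=cfg, loss_history=list(meta["loss_history"]))


def extract_shallow_subvolumes(
    stack: ImageStack,
    cfg: DiffusionConfig,
    seed: int,
    n_patches: int = 64,
) -> list[np.ndarray]:
    """Sample seeded training patches from the shallow fraction of a stack.

    Only the first ``ceil(shallow_fraction * n_frames)`` frames are eligible.
    Patches are normalized to [0, 1] by the stack-wide min–max transform.
    """
    if stack.n_frames < 2:
        raise ValueError("stack must have at least 2 frames")
    ph = cfg.patch_size
    nz, ny, nx = stack.shape
    if ph > ny or ph > nx:
        raise ValueError(f"patch size {ph} larger than frame {(ny, nx)}")
    n_shallow = max(int(np.ceil(cfg.shallow_fraction * nz)), 1)
    norm, _ = stack.normalized()
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n_patches):
        k = int(rng.integers(0, n_shallow))
        y = int(rng.integers(0, ny - ph + 1))
        x = int(rng.integers(0, nx - ph + 1))
        patches.append(norm.voxels[k, y : y + ph, x : x + ph].copy())
    return patches


def augment(
    patches: list[np.ndarray],
    flips: bool = True,
    rotations: bool = True,
    seed: int = 0,
) -> list[np.ndarray]:
    """Deterministic dihedral augmentation of square patches.

    With both flips and rotations enabled each patch yields its full 8-element
    dihedral orbit (originals included); flips alone give 4 variants,
    rotations alone 4.  With neither flag the input is returned unchanged.
    The output order is deterministic for a fixed seed.
    """
    if not patches:
        raise ValueError("patch list must be non-empty")
    if not flips and not rotations:
        return list(patches)
    out: list[np.ndarray] = []
    for p in patches:
        variants: list[np.ndarray] = []
        if rotations:
            variants.extend(np.rot90(p, k) for k in range(4))
        else:
            variants.append(p)
        if flips:
            variants = [v for w in variants for v in (w, np.fliplr(w))]
            if not rotations:
                variants = [p, np.fliplr(p), np.flipud(p), np.flipud(np.fliplr(p))]
        out.extend(np.ascontiguousarray(v) for v in variants)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def forward_diffuse(
    x0: np.ndarray, t: int, cfg: DiffusionConfig, noise: np.ndarray
) -> np.ndarray:
    """Closed-form forward marginal ``x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps``."""
    if not 1 <= t <= cfg.T:
        raise IndexError(f"t={t} outside 1..{cfg.T}")
    x0 = np.asarray(x0, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != x0.shape:
        raise ValueError("noise draw must match x0's shape")
    abar = cfg.alpha_bars()[t - 1]
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * noise


def train(
    patches: list[np.ndarray],
    cfg: DiffusionConfig,
    seed: int = 0,
) -> DenoiserModel:
    """Train the noise-prediction U-Net on clean patches.

    Loss is the mean squared error between the injected standard-normal
    noise and the network's prediction at uniformly sampled steps t.  All
    randomness (init, batching, t, noise) derives from ``seed``; equal seeds
    give identical loss histories.  Patches are expected in [0, 1] and are
    mapped to [-1, 1] internally.
    """
    if not patches:
        raise ValueError("need at least one training patch")
    init_seed, loop_seed = spawn_seeds(seed, 2)
    net = UNet(cfg.base_channels, cfg.channel_mults, seed=init_seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(loop_seed)
    abars = cfg.alpha_bars()

    data = np.stack([np.asarray(p, dtype=np.float64) for p in patches])[:, None] * 2.0 - 1.0
    n = len(data)
    bs = min(cfg.batch_size, n)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            x0 = data[idx]
            t = rng.integers(1, cfg.T + 1, size=len(idx))
            eps = rng.standard_normal(x0.shape)
            ab = abars[t - 1][:, None, None, None]
            xt = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps
            pred = net(Tensor(xt), t)
            diff = pred - Tensor(eps)
            loss = ad.mean(ad.mul(diff, diff))
            if not np.isfinite(loss.data):
                raise TrainingError(f"loss diverged (NaN/inf) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        logger.info("diffusion train epoch %d/%d: loss %.5f", epoch + 1, cfg.epochs, history[-1])
    return DenoiserModel(net=net, config=cfg, loss_history=history)


def estimate_t_start(frame: np.ndarray, cfg: DiffusionConfig) -> int:
    """Choose the diffusion step whose marginal noise matches the frame's.

    The residual noise level is estimated as the robust (MAD-based) standard
    deviation of horizontal first differences of the [-1, 1]-scaled frame;
    the returned t is the smallest with ``sqrt(1 - abar_t)`` at or above
    that estimate (clamped to [1, T]).
    """
    f = np.asarray(frame, dtype=np.float64) * 2.0 - 1.0
    d = np.diff(f, axis=1).ravel()
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    marg = np.sqrt(1.0 - cfg.alpha_bars())
    idx = np.searchsorted(marg, sigma)
    return int(np.clip(idx + 1, 1, cfg.T))


def _pad_to_multiple(frame: np.ndarray, m: int = 8) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = frame.shape
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        frame = np.pad(frame, ((0, ph), (0, pw)), mode="reflect")
    return frame, (h, w)


def _reverse_batch(
    x: np.ndarray,
    model: DenoiserModel,
    t_start: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ancestral sampling of a (N, 1, H, W) batch in [-1, 1] from t_start to 0."""
    cfg = model.config
    betas = cfg.betas()
    alphas = 1.0 - betas
    abars = cfg.alpha_bars()
    n = x.shape[0]
    with ad.no_grad():
        for t in range(t_start, 0, -1):
            eps_hat = model.net(Tensor(x), np.full(n, t)).data
            a_t, ab_t = alphas[t - 1], abars[t - 1]
            x = (x - betas[t - 1] / np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(a_t)
            if t > 1:
                ab_prev = abars[t - 2]
                var = betas[t - 1] * (1.0 - ab_prev) / (1.0 - ab_t)
                x = x + np.sqrt(var) * rng.standard_normal(x.shape)
    return x


def reverse_denoise(
    image: np.ndarray,
    model: DenoiserModel,
    t_start: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Ancestral DDPM sampling initialized at the input image.

    The [0, 1] image is mapped to [-1, 1], treated as ``x_{t_start}`` and
    sampled down to t=0 with the trained noise predictor; the final sample is
    mapped back to [0, 1].  ``t_start=None`` uses the noise-adaptive choice.
    """
    cfg = model.config
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("reverse_denoise expects a single 2D frame")
    if t_start is None:
        t_start = estimate_t_start(img, cfg)
    if not 1 <= t_start <= cfg.T:
        raise IndexError(f"t_start={t_start} outside 1..{cfg.T}")

    padded, (h, w) = _pad_to_multiple(img)
    x = padded[None, None] * 2.0 - 1.0
    x = _reverse_batch(x, model, t_start, np.random.default_rng(seed))
    out = (x[0, 0] + 1.0) / 2.0
    return out[:h, :w]


def neighbor_depth_average(
    stack: ImageStack, radius: int, gain_match: bool = False
) -> ImageStack:
    """Uniform running mean over ±``radius`` neighboring frames (edge-truncated).

    With ``gain_match`` each neighbor is rescaled to the center frame's mean
    intensity before averaging.  Under depth-dependent attenuation plain
    averaging mixes dimmer (deeper) frames into brighter ones, diluting the
    signal while the depth-independent additive background is unchanged;
    gain matching keeps each frame's intensity scale while still averaging
    down the uncorrelated noise.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return stack.copy()
    v = stack.voxels
    out = np.empty_like(v)
    means = v.mean(axis=(1, 2))
    for k in range(stack.n_frames):
        lo, hi = max(0, k - radius), min(stack.n_frames, k + radius + 1)
        if gain_match and means[k] > 0:
            gains = np.array([means[k] / m if m > 0 else 1.0 for m in means[lo:hi]])
            out[k] = (v[lo:hi] * gains[:, None, None]).mean(axis=0)
        else:
            out[k] = v[lo:hi].mean(axis=0)
    return ImageStack(out, stack.z_step, stack.z0_depth, stack.source_dtype)


def lrdm_enhance(
    stack: ImageStack,
    model: DenoiserModel,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    t_start: int | None = None,
    collect_stages: bool = False,
) -> ImageStack | tuple[ImageStack, dict]:
    """Full enhancement: stripe removal -> depth averaging -> reverse diffusion.

    Per-frame reverse-diffusion seeds are derived from ``seed``; with
    ``collect_stages`` the per-stage intermediates and stripe reports are
    returned alongside the enhanced stack.
    """
    cfg = cfg or PipelineConfig()
    destriped, reports = lr_denoise_stack(stack, cfg.lr_ratio_threshold)
    averaged = neighbor_depth_average(destriped, cfg.neighbor_avg_radius, gain_match=True)
    # Each frame is min-max normalized individually before entering the
    # reverse process (deep, attenuated frames are thereby brought onto the
    # intensity scale the network saw in training); the affine transform is
    # inverted afterwards, so the output keeps the stack's depth profile.
    h, w = averaged.voxels.shape[1:]
    frames_norm = np.empty_like(averaged.voxels)
    scales: list[tuple[float, float]] = []
    for k in range(averaged.n_frames):
        f = averaged.voxels[k]
        lo, hi = float(f.min()), float(f.max())
        frames_norm[k] = (f - lo) / (hi - lo) if hi > lo else 0.0
        scales.append((lo, hi))
    t_used = [
        t_start if t_start is not None else estimate_t_start(frames_norm[k], model.config)
        for k in range(averaged.n_frames)
    ]
    # frames sharing a t_start are denoised as one batch (chunked for memory)
    out = np.empty_like(frames_norm)
    group_seeds = spawn_seeds(seed, model.config.T + 1)
    for ts in sorted(set(t_used)):
        idx = [k for k, t in enumerate(t_used) if t == ts]
        rng = np.random.default_rng(group_seeds[ts % len(group_seeds)])
        for start in range(0, len(idx), 8):
            chunk = idx[start : start + 8]
            frames = np.stack([_pad_to_multiple(frames_norm[k])[0] for k in chunk])
            res = _reverse_batch(frames[:, None] * 2.0 - 1.0, model, ts, rng)
            for j, k in enumerate(chunk):
                lo, hi = scales[k]
                out[k] = np.clip((res[j, 0, :h, :w] + 1.0) / 2.0, 0.0, None) * (hi - lo) + lo
    enhanced_v = np.clip(out, 0.0, None)
    enhanced = ImageStack(enhanced_v, stack.z_step, stack.z0_depth, stack.source_dtype)
    if collect_stages:
        stages = {
            "stripe_reports": reports,
            "destriped": destriped,
            "averaged": averaged,
            "t_start": t_used,
        }
        return enhanced, stages
    return enhanced
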