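"""Time-conditioned U-Net noise predictor for the diffusion denoiser.

Architecture: four feature-map resolutions (full size down to 1/8) with two
convolutional residual blocks per level, self-attention between the two
blocks at the 1/4-resolution level, and a Transformer-style sinusoidal
position embedding of the diffusion step t added into every residual block.
The network is fully convolutional, so a model trained on one patch size
runs on any input whose sides are multiples of 8.

Implemented on the package's numpy autodiff engine; weights live in plain
float64 arrays, and checkpoints are .npz archives that round-trip
bit-exactly.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["UNet", "sinusoidal_embedding"]


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Transformer sinusoidal position embedding of step indices t, shape (n, dim)."""
    t = np.asarray(t, dtype=np.float64).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)


class Param(Tensor):
    """A leaf tensor tracked by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Param]:
        params: list[Param] = []

        def visit(v) -> None:
            if isinstance(v, Param):
                params.append(v)
            elif isinstance(v, Module):
                for p in v.parameters():
                    params.append(p)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    visit(item)

        for v in self.__dict__.values():
            visit(v)
        # dedupe while preserving order (shared/aliased submodules)
        seen: set[int] = set()
        unique: list[Param] = []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                unique.append(p)
        return unique


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, scale: float = 1.0):
        fan_in = cin * k * k
        self.w = Param(rng.normal(0, scale / np.sqrt(fan_in), size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, scale: float = 1.0):
        self.w = Param(rng.normal(0, scale / np.sqrt(cin), size=(cin, cout)))
        self.b = Param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.w), self.b)


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.groups = groups
        self.eps = eps
        self.gamma = Param(np.ones((1, channels, 1, 1)))
        self.beta = Param(np.zeros((1, channels, 1, 1)))

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        g = self.groups
        xg = ad.reshape(x, (n, g, c // g, h, w))
        mu = ad.mean(xg, axis=(2, 3, 4), keepdims=True)
        xc = ad.sub(xg, mu)
        var = ad.mean(ad.mul(xc, xc), axis=(2, 3, 4), keepdims=True)
        inv = ad.pow_(ad.add(var, Tensor(self.eps)), -0.5)
        xn = ad.reshape(ad.mul(xc, inv), (n, c, h, w))
        return ad.add(ad.mul(xn, self.gamma), self.beta)


class ResBlock(Module):
    """norm -> silu -> conv3x3 -> (+ time bias) -> norm -> silu -> conv3x3, with skip."""

    def __init__(self, cin: int, cout: int, t_dim: int, rng: np.random.Generator):
        self.n1 = GroupNorm(cin)
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.t_proj = Linear(t_dim, cout, rng)
        self.n2 = GroupNorm(cout)
        self.c2 = Conv2d(cout, cout, 3, rng, scale=0.1)
        self.skip = Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor, t_emb: Tensor) -> Tensor:
        h = self.c1(ad.silu(self.n1(x)))
        tb = self.t_proj(ad.silu(t_emb))  # (N, cout)
        tb = ad.reshape(tb, (tb.data.shape[0], tb.data.shape[1], 1, 1))
        h = ad.add(h, tb)
        h = self.c2(ad.silu(self.n2(h)))
        s = self.skip(x) if self.skip is not None else x
        return ad.add(h, s)


class SelfAttention(Module):
    """Single-head self-attention over spatial positions."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.norm = GroupNorm(channels)
        self.qkv = Conv2d(channels, 3 * channels, 1, rng)
        self.proj = Conv2d(channels, channels, 1, rng, scale=0.1)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        qkv = self.qkv(self.norm(x))  # (N, 3C, H, W)
        flat = ad.reshape(qkv, (n, 3 * c, h * w))
        q = ad.transpose(_narrow(flat, 0, c), (0, 2, 1))  # (N, HW, C)
        k = _narrow(flat, c, 2 * c)  # (N, C, HW)
        v = _narrow(flat, 2 * c, 3 * c)  # (N, C, HW)
        attn = ad.softmax(ad.mul(ad.matmul(q, k), Tensor(1.0 / np.sqrt(c))), axis=-1)
        out = ad.matmul(v, ad.transpose(attn, (0, 2, 1)))  # (N, C, HW)
        out = ad.reshape(out, (n, c, h, w))
        return ad.add(x, self.proj(out))


def _narrow(t: Tensor, lo: int, hi: int) -> Tensor:
    """Slice channels [lo:hi] of a (N, C, L) tensor."""
    def backward(g):
        full = np.zeros_like(t.data)
        full[:, lo:hi] = g
        ad._accum(t, full)
    return ad._make(t.data[:, lo:hi], (t,), backward)


class UNet(Module):
    """Noise predictor eps_theta(x_t, t).

    ``channel_mults`` fixes one multiplier per resolution level (4 levels);
    attention sits between the two residual blocks of the 1/4-resolution
    level (index 2).
    """

    ATTN_LEVEL = 2

    def __init__(self, base_channels: int = 16, channel_mults=(1, 2, 2, 4), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.base_channels = base_channels
        self.channel_mults = tuple(channel_mults)
        t_dim = base_channels * 4
        self.t_dim = t_dim
        self.t_mlp1 = Linear(base_channels, t_dim, rng)
        self.t_mlp2 = Linear(t_dim, t_dim, rng)

        chans = [base_channels * m for m in channel_mults]
        self.conv_in = Conv2d(1, chans[0], 3, rng)

        self.down_blocks: list[list[Module]] = []
        self.down_attn: list[Module | None] = []
        cin = chans[0]
        for lvl, ch in enumerate(chans):
            b1 = ResBlock(cin, ch, t_dim, rng)
            b2 = ResBlock(ch, ch, t_dim, rng)
            self.down_blocks.append([b1, b2])
            self.down_attn.append(SelfAttention(ch, rng) if lvl == self.ATTN_LEVEL else None)
            cin = ch

        self.mid1 = ResBlock(chans[-1], chans[-1], t_dim, rng)
        self.mid2 = ResBlock(chans[-1], chans[-1], t_dim, rng)

        self.up_blocks: list[list[Module]] = []
        self.up_attn: list[Module | None] = []
        self.up_convs: list[Module] = []
        cin = chans[-1]
        for lvl in reversed(range(len(chans))):
            ch = chans[lvl]
            self.up_convs.append(Conv2d(cin, ch, 3, rng))
            b1 = ResBlock(2 * ch, ch, t_dim, rng)  # concatenated skip
            b2 = ResBlock(ch, ch, t_dim, rng)
            self.up_blocks.append([b1, b2])
            self.up_attn.append(SelfAttention(ch, rng) if lvl == self.ATTN_LEVEL else None)
            cin = ch

        self.norm_out = GroupNorm(chans[0])
        self.conv_out = Conv2d(chans[0], 1, 3, rng, scale=0.1)

    def __call__(self, x: Tensor, t: np.ndarray) -> Tensor:
        """Predict the noise in ``x`` (N, 1, H, W) at step indices ``t`` (N,)."""
        emb = Tensor(sinusoidal_embedding(t, self.base_channels))
        emb = self.t_mlp2(ad.silu(self.t_mlp1(emb)))

        h = self.conv_in(x)
        skips: list[Tensor] = []
        for lvl, (b1, b2) in enumerate(self.down_blocks):
            h = b1(h, emb)
            if self.down_attn[lvl] is not None:
                h = self.down_attn[lvl](h)
            h = b2(h, emb)
            skips.append(h)
            if lvl < len(self.down_blocks) - 1:
                h = ad.avg_pool2(h)

        h = self.mid1(h, emb)
        h = self.mid2(h, emb)

        for i, (b1, b2) in enumerate(self.up_blocks):
            lvl = len(self.down_blocks) - 1 - i
            if i > 0:
                h = ad.upsample2(h)
            h = self.up_convs[i](h)
            h = b1(ad.concat([h, skips[lvl]], axis=1), emb)
            if self.up_attn[i] is not None:
                h = self.up_attn[i](h)
            h = b2(h, emb)

        return self.conv_out(ad.silu(self.norm_out(h)))

    # --- persistence -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"checkpoint has {len(state)} arrays, model needs {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr


class Adam:
    """Adaptive moment estimation optimizer."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
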