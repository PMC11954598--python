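"""Diffusion denoiser: forward-marginal correctness, self-supervision, training, sampling."""

import numpy as np
import pytest

from deepvessel import (
    DiffusionConfig,
    ImageStack,
    PipelineConfig,
    augment,
    extract_shallow_subvolumes,
    forward_diffuse,
    lrdm_enhance,
    neighbor_depth_average,
    reverse_denoise,
)
from deepvessel.diffusion import DenoiserModel, estimate_t_start, train

TINY = dict(
    T=8,
    epochs=3,
    patch_size=16,
    base_channels=4,
    channel_mults=(1, 1, 1, 1),
    batch_size=8,
    learning_rate=1e-3,
)


@pytest.fixture(scope="module")
def tiny_model(request):
    rng = np.random.default_rng(0)
    patches = [np.clip(rng.random((16, 16)) * 0.2, 0, 1) for _ in range(16)]
    return train(patches, DiffusionConfig(**TINY), seed=5)


class TestForwardDiffuse:
    def test_zero_signal_case(self, rng):
        cfg = DiffusionConfig(T=10)
        eps = rng.standard_normal((8, 8))
        xt = forward_diffuse(np.zeros((8, 8)), 5, cfg, eps)
        abar = cfg.alpha_bars()[4]
        assert np.allclose(xt, np.sqrt(1 - abar) * eps)

    def test_near_identity_at_small_t(self, rng):
        cfg = DiffusionConfig(T=10, beta_start=1e-8, beta_end=1e-8)
        x0 = rng.random((8, 8))
        xt = forward_diffuse(x0, 1, cfg, rng.standard_normal((8, 8)))
        assert np.allclose(xt, x0, atol=1e-3)

    def test_t_out_of_range(self, rng):
        cfg = DiffusionConfig(T=10)
        with pytest.raises(IndexError):
            forward_diffuse(np.zeros((4, 4)), 11, cfg, np.zeros((4, 4)))
        with pytest.raises(IndexError):
            forward_diffuse(np.zeros((4, 4)), 0, cfg, np.zeros((4, 4)))

    @pytest.mark.parametrize("t_frac", [0.0, 0.5, 1.0])
    def test_marginal_moments_monte_carlo(self, t_frac):
        """Sample mean/variance of x_t match the closed form within 3 SE."""
        cfg = DiffusionConfig(T=200)
        t = max(1, int(round(t_frac * cfg.T)))
        x0 = 0.3
        n = 10_000
        rng = np.random.default_rng(99)
        eps = rng.standard_normal(n)
        xt = forward_diffuse(np.full(n, x0), t, cfg, eps)
        abar = cfg.alpha_bars()[t - 1]
        mean_se = np.sqrt(1 - abar) / np.sqrt(n)
        assert abs(xt.mean() - np.sqrt(abar) * x0) < 3 * mean_se
        var = xt.var(ddof=1)
        var_se = (1 - abar) * np.sqrt(2 / (n - 1))
        assert abs(var - (1 - abar)) < 3 * var_se


class TestShallowExtraction:
    def test_only_shallow_frames_sampled(self):
        # deep frames carry a bright sentinel; shallow values stay below 0.5
        voxels = np.full((100, 32, 32), 1.0)
        voxels[:20] = 0.4
        stack = ImageStack(voxels)
        cfg = DiffusionConfig(**TINY, shallow_fraction=0.2)
        patches = extract_shallow_subvolumes(stack, cfg, seed=3, n_patches=40)
        assert len(patches) == 40
        assert all(p.max() <= 0.45 for p in patches)

    def test_full_fraction_reaches_deep_frames(self):
        voxels = np.full((10, 32, 32), 0.1)
        voxels[-1] = 1.0
        stack = ImageStack(voxels)
        cfg = DiffusionConfig(**TINY, shallow_fraction=1.0)
        patches = extract_shallow_subvolumes(stack, cfg, seed=3, n_patches=200)
        assert any(p.max() > 0.9 for p in patches)

    def test_patch_larger_than_frame_rejected(self):
        stack = ImageStack(np.ones((4, 8, 8)))
        with pytest.raises(ValueError):
            extract_shallow_subvolumes(stack, DiffusionConfig(**TINY), seed=0)

    def test_determinism(self):
        stack = ImageStack(np.random.default_rng(0).random((20, 32, 32)))
        cfg = DiffusionConfig(**TINY)
        a = extract_shallow_subvolumes(stack, cfg, seed=9)
        b = extract_shallow_subvolumes(stack, cfg, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestAugment:
    def test_flags_off_identity(self, rng):
        patches = [rng.random((8, 8))]
        assert augment(patches, flips=False, rotations=False) == patches

    def test_dihedral_group_order(self, rng):
        p = rng.random((8, 8))
        out = augment([p], flips=True, rotations=True, seed=0)
        assert len(out) == 8
        uniq = {a.tobytes() for a in out}
        assert len(uniq) == 8  # all distinct for a generic patch

    def test_determinism(self, rng):
        patches = [rng.random((8, 8)) for _ in range(3)]
        a = augment(patches, seed=4)
        b = augment(patches, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            augment([])


class TestTraining:
    def test_loss_decreases_on_smoke_run(self, tiny_model):
        h = tiny_model.loss_history
        assert len(h) == TINY["epochs"]
        assert h[-1] < h[0]

    def test_zero_epochs_rejected(self):
        with pytest.raises(Exception):
            DiffusionConfig(**{**TINY, "epochs": 0})

    def test_identical_seeds_identical_histories(self):
        rng = np.random.default_rng(0)
        patches = [rng.random((16, 16)) for _ in range(8)]
        cfg = DiffusionConfig(**{**TINY, "epochs": 2})
        m1 = train(patches, cfg, seed=7)
        m2 = train(patches, cfg, seed=7)
        assert m1.loss_history == m2.loss_history

    def test_checkpoint_round_trip_preserves_predictions(self, tiny_model, tmp_path, rng):
        p = tmp_path / "model.ckpt"
        tiny_model.save(p)
        again = DenoiserModel.load(p)
        frame = rng.random((16, 16))
        a = reverse_denoise(frame, tiny_model, t_start=3, seed=1)
        b = reverse_denoise(frame, again, t_start=3, seed=1)
        assert np.array_equal(a, b)
        assert again.loss_history == tiny_model.loss_history


class TestReverseDenoise:
    def test_near_identity_at_minimal_t(self, tiny_model, rng):
        frame = rng.random((16, 16)) * 0.5 + 0.25
        out = reverse_denoise(frame, tiny_model, t_start=1, seed=0)
        rel = np.abs(out - frame).mean() / frame.mean()
        assert rel < 0.05

    def test_seeded_reproducibility(self, tiny_model, rng):
        frame = rng.random((16, 16))
        a = reverse_denoise(frame, tiny_model, t_start=5, seed=3)
        b = reverse_denoise(frame, tiny_model, t_start=5, seed=3)
        assert np.array_equal(a, b)

    def test_t_start_out_of_range(self, tiny_model):
        with pytest.raises(IndexError):
            reverse_denoise(np.zeros((16, 16)), tiny_model, t_start=99)

    def test_non_multiple_of_eight_shapes_supported(self, tiny_model, rng):
        frame = rng.random((19, 21))
        out = reverse_denoise(frame, tiny_model, t_start=2, seed=0)
        assert out.shape == (19, 21)
        assert np.all(np.isfinite(out))

    def test_adaptive_t_start_scales_with_noise(self, rng):
        cfg = DiffusionConfig(T=50)
        base = np.clip(0.5 + 0.02 * rng.standard_normal((64, 64)), 0, 1)
        noisy = np.clip(0.5 + 0.3 * rng.standard_normal((64, 64)), 0, 1)
        assert estimate_t_start(noisy, cfg) > estimate_t_start(base, cfg)


class TestEnhancePipeline:
    def test_neighbor_average_radius_zero_identity(self, rng):
        stack = ImageStack(rng.random((5, 8, 8)))
        out = neighbor_depth_average(stack, 0)
        assert np.array_equal(out.voxels, stack.voxels)

    def test_neighbor_average_uniform_window(self):
        v = np.zeros((5, 2, 2))
        for k in range(5):
            v[k] = k
        out = neighbor_depth_average(ImageStack(v), 1)
        assert out.voxels[2, 0, 0] == pytest.approx(2.0)
        assert out.voxels[0, 0, 0] == pytest.approx(0.5)  # edge-truncated

    def test_gain_matched_average_preserves_attenuated_scale(self):
        # constant frames under exponential decay: gain matching makes the
        # average a no-op, plain averaging drags each frame toward neighbors
        v = np.stack([np.full((4, 4), np.exp(-k / 2)) for k in range(6)])
        stack = ImageStack(v)
        matched = neighbor_depth_average(stack, 1, gain_match=True)
        assert np.allclose(matched.voxels, v)
        plain = neighbor_depth_average(stack, 1, gain_match=False)
        assert not np.allclose(plain.voxels, v)

    def test_identity_composition(self, tiny_model, rng):
        """No stripes, no averaging, minimal t: the pipeline is near-identity."""
        yy, xx = np.mgrid[0:16, 0:16]
        frames = [
            0.05 + 0.7 * np.exp(-((yy - xx + c) ** 2) / 8) + 0.1 * rng.random((16, 16))
            for c in (-4, 0, 4)
        ]
        stack = ImageStack(np.stack(frames))
        cfg = PipelineConfig(neighbor_avg_radius=0, diffusion=DiffusionConfig(**TINY))
        out = lrdm_enhance(stack, tiny_model, cfg, seed=0, t_start=1)
        rel = np.abs(out.voxels - stack.voxels).mean() / stack.voxels.mean()
        assert rel < 0.1

    def test_enhance_deterministic(self, tiny_model, rng):
        stack = ImageStack(rng.random((4, 16, 16)))
        cfg = PipelineConfig(diffusion=DiffusionConfig(**TINY))
        a = lrdm_enhance(stack, tiny_model, cfg, seed=2)
        b = lrdm_enhance(stack, tiny_model, cfg, seed=2)
        assert np.array_equal(a.voxels, b.voxels)
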