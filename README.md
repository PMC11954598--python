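# deepvessel

Restoration and 3D vascular morphometry for deep three-photon microscopy
(3PM) z-stacks.

Fluorescence imaging deep in scattering tissue degrades in two distinct
ways: detector ripple is modulated by the raster line scan into *stripe
noise* (constant along the fast-scan axis within each line), and the
photon-starved signal drowns in *random noise* as depth grows. Because the
two families have different structure, this package removes them with two
dedicated stages and then quantifies the recovered vasculature:

1. **Low-rank stripe denoiser** — each 2D frame `X = U S Vᵀ` is gated on
   the singular-value ratio σ1/σ2 ≥ 3 (a stripe-dominated frame is nearly
   rank-1); gated frames are rebuilt with σ1 replaced by σ2, suppressing
   the periodic structure. Ungated frames pass through bit-identical.
2. **Self-supervised diffusion denoiser** — a DDPM whose training data are
   patches from the stack's own *shallow side* (the frames nearest the
   objective, with the best image quality). Forward process
   `x_t = √ᾱ_t x0 + √(1−ᾱ_t) ε`; a time-conditioned U-Net (4 resolutions,
   2 residual blocks per level, self-attention at 1/4 resolution,
   sinusoidal t-embedding) predicts ε. A degraded frame enters ancestral
   sampling as `x_{t_start}`, with `t_start` chosen per frame from a robust
   noise estimate.
3. **3D morphometry** — from a binary segmentation `A`, its skeleton `S`
   and surface `P`, five voxel-wise metrics are evaluated in sliding cubic
   windows of side n: VVD = ΣA/n³, VTI = ΣA/ΣS, VSD = ΣS/n³,
   VCI = (ΣP)²/(4π·ΣA), VSI = ΣP/n³.
4. **Region classification** — a linear SVM on the five-metric feature
   vectors labels windows as neocortex (1), white matter (2) or
   hippocampus (3), and region boundary depths are read off label-count
   crossovers along depth.

Because deep in vivo stacks cannot ship with the package, a first-class
phantom module generates tubular vessel volumes and degrades them with the
same noise structure (depth attenuation, scattering glow, line-wise
stripes, Poisson shot + readout noise), giving paired clean/noised data
for validation. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

```python
import numpy as np
from deepvessel import *
from deepvessel.diffusion import augment, extract_shallow_subvolumes, train

# paired phantom: clean vessels + deep-imaging degradation
clean, truth = generate_vessels(PhantomConfig(shape=(32, 64, 64)), seed=42)
noised = degrade(clean, truth, DegradationConfig(), seed=7)

# self-supervised training on the stack's own shallow side
cfg = DiffusionConfig(T=25, epochs=30, patch_size=32, base_channels=8,
                      channel_mults=(1, 1, 2, 2), learning_rate=1.5e-3)
patches = augment(extract_shallow_subvolumes(noised, cfg, seed=1, n_patches=24),
                  seed=2)
model = train(patches, cfg, seed=3)

# full enhancement: destripe -> depth-average -> reverse diffusion
enhanced = lrdm_enhance(noised, model, PipelineConfig(diffusion=cfg), seed=4)

bg = background_mask_from_truth(truth)
for name, stack in [("raw", noised), ("enhanced", enhanced)]:
    prof = sbr_depth_profile(stack, truth.voxels, bg.voxels, bin_frames=8)
    print(name, [round(s, 2) for _, s in prof])
print("F1 raw     ", round(f1(confusion(otsu_segment(noised, per_frame=True), truth)), 3))
print("F1 enhanced", round(f1(confusion(otsu_segment(enhanced, per_frame=True), truth)), 3))
```

Output:

```
raw [5.15, 4.18, 3.05, 2.24]
enhanced [5.17, 6.11, 6.43, 5.0]
F1 raw      0.271
F1 enhanced 0.665
```

The raw stack's signal-to-background ratio collapses with depth (the
phantom's attenuation compresses a millimeter-scale decline into 64 µm);
after enhancement the deep bins recover to near-shallow contrast, and
per-slice Otsu segmentation of the vessels more than doubles its F1 score
against the ground-truth mask.

The same pipeline is scriptable from the shell:

```sh
deepvessel phantom --out data/ --seed 3
deepvessel denoise-lr data/noised_000.tif destriped.tif --report report.json
deepvessel train --stack data/noised_000.tif --out model.ckpt
deepvessel enhance --stack data/noised_000.tif --model model.ckpt --out enhanced.tif
deepvessel segment enhanced.tif --method otsu --out mask.tif
deepvessel quantify --mask mask.tif --window 32 --csv metrics.csv
```

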