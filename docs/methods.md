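# Methods

`deepvessel` restores deep three-photon microscopy (3PM) z-stacks and
quantifies the segmented vasculature in 3D. This note documents the models
the package implements, the parameters that matter, what the synthetic
phantoms do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Noise model of deep 3PM stacks

A raster-scanned fluorescence frame acquired deep in scattering tissue is
modeled as a clean signal corrupted by two distinct noise families:

* **Structured (stripe) noise.** Detector-side ripple is modulated by the
  line scan into a field that is constant along the fast-scan axis `x`
  within each line `y`. Within one 2D frame this field is (close to)
  rank-1, so it concentrates in the largest singular value of the frame.
* **Random noise.** Photon-limited shot noise plus Gaussian readout noise,
  increasingly dominant with depth as the ballistic signal attenuates.

The two families are removed by two dedicated stages, in this order,
because a diffusion model built on pixel-independence assumptions will
reproduce or amplify structured noise if it is still present.

## Low-rank stripe denoiser

Each frame `X` (transposed when needed so M ≥ N) is decomposed as
`X = U S Vᵀ` with singular values σ1 ≥ σ2 ≥ … ≥ σr ≥ 0. Frames are *gated*
on the ratio σ1/σ2 ≥ τ (default τ = 3, inclusive): a stripe-dominated frame
has a top singular value that stands far above the rest, whereas a normal
frame has a flatter spectrum. Gated frames are rebuilt with σ1 replaced by
σ2 (optionally the top k values by σ_{k+1}), which makes the new top ratio
exactly 1 — the operation is therefore idempotent and never increases the
Frobenius norm. Ungated frames pass through bit-identical.

Open choices, resolved as follows: the replacement value is σ2 (minimal,
idempotent; exposed as `n_replace`); the gate is evaluated per frame, not
per stack; σ2 below the numerical-rank tolerance counts as zero, and such a
pure rank-1 frame is zeroed (it is all structure under this model).

One caveat worth knowing: σ1 of a natural non-negative image also carries
the DC (mean) component, so on frames with a strong uniform background the
ratio can exceed τ without stripes. In practice deep vascular frames are
sparse and textured, keeping ungated ratios near 2; the gate exists
precisely to separate these regimes.

## Self-supervised diffusion denoiser

Random noise is removed by a denoising diffusion probabilistic model
(DDPM) trained **only on the stack being processed**: training patches are
drawn from the *shallow side* (the first `shallow_fraction`, default 20%,
of frames — those nearest the objective, with the best image quality).
No external clean data is used.

* **Forward process:** `x_t = √ᾱ_t x0 + √(1−ᾱ_t) ε`, `ε ~ N(0, I)`, with a
  linear β schedule 1e-4 → 2e-2 over `T` steps (default T = 200; desk-scale
  runs use T = 25 — the schedule is resolution- and length-relative).
* **Network:** a time-conditioned U-Net with four feature-map resolutions
  (full → 1/8), two convolutional residual blocks per level, single-head
  self-attention between the two blocks of the 1/4-resolution level, and a
  Transformer sinusoidal embedding of t added into every residual block.
  The network is fully convolutional and resolution-relative: a model
  trained on 32-px patches runs on any frame whose sides are multiples
  of 8. It is implemented on a small in-package reverse-mode autodiff
  engine over numpy (convolution via im2col, gradients verified against
  finite differences in the test suite), with Adam as the optimizer.
* **Loss:** mean squared error between injected and predicted noise at
  uniformly sampled t; patches are mapped from [0, 1] to [−1, 1].
* **Augmentation:** the dihedral group (flips + 90° rotations, 8 variants
  per patch), deterministic under the run seed.

**Inference.** A degraded frame is treated as a partially diffused sample
`x_{t_start}` and run through ancestral sampling down to t = 0. Because the
appropriate entry step is not knowable a priori, `t_start` is chosen per
frame from a robust noise estimate: the MAD-based standard deviation of
horizontal first differences (divided by √2), matched to the smallest t
with `√(1−ᾱ_t)` at or above it. Nearly clean frames thus enter at t ≈ 1 and
pass through almost unchanged; a fixed `t_start` override is available.

**Full enhancement pipeline** (`lrdm_enhance`): low-rank stripe removal →
gain-matched neighbor-depth averaging over ±`neighbor_avg_radius` frames
(default ±1) → per-frame reverse diffusion. In the averaging stage each
neighbor frame is rescaled to the center frame's mean intensity first:
under depth-dependent attenuation a plain mean mixes dimmer (deeper)
frames into brighter ones, diluting signal while the depth-independent
additive background stays put; gain matching keeps each frame's intensity
scale while still averaging down uncorrelated noise. Each frame is min–max
normalized individually before entering the reverse process — deep,
attenuated frames are thereby brought onto the intensity scale the network
saw during training, which is what lets shallow image statistics compensate
deep frames — and the affine transform is inverted afterwards so the
output keeps the stack's physical depth profile. Frames sharing a
`t_start` are batched for speed.

## Vessel phantoms and the degradation model

Real deep-brain stacks cannot ship with the package, so validation runs on
synthetic phantoms with the same degradation structure.

**Geometry.** Tubular vessels swept along smooth random-walk centerlines
(step 2 voxels, direction jitter set by `tortuosity`, optional branching),
rasterized by exact distance-to-centerline thresholding (verified against
a brute-force per-voxel oracle). Clean intensity: `vessel_intensity` = 1.0
on vessels over `background_level` = 0.05, with a 1-voxel soft rim.

**Degradation**, applied per frame at relative depth z:

1. exponential attenuation `exp(−z / attenuation_length)`;
2. Gaussian blur (σ = 1.5 px) plus a diffuse scattering glow — a
   wide-blurred copy of the signal added back at `scatter_fraction` = 0.5;
3. a line-wise sinusoidal stripe field (period 8 lines, amplitude 0.15,
   random phase per frame), constant along x within each line;
4. Poisson shot noise at `photon_scale` = 50 expected photons per unit
   intensity, then Gaussian readout noise (σ = 0.03), clipped at 0.

Defaults are chosen once to make a desk-scale stack (64 µm deep, 2 µm
z-step) traverse the regime deep imaging traverses over millimeters: the
attenuation length of 30 µm takes the raw signal-to-background ratio (SBR)
from ≈ 8–15 at the surface to ≈ 2 at the bottom — the same sharp decline,
compressed in depth — with stripe amplitude comparable to the attenuated
vascular signal at mid-depth. The waveform of the ripple field is a
sinusoid (the physical provenance constrains only its line-wise structure).

**SBR targeting.** `target_sbr` solves for a single global noise
multiplier by bisection, measuring SBR against the ground-truth masks
(background = voxels ≥ 3 voxels from any vessel). The signal-correlated
scatter glow is only ever scaled *down* by the multiplier; the
signal-independent terms (stripes, pedestal, readout) grow beyond their
configured levels, so the achievable SBR spans from the blur-limited
ceiling down to 1 and any target in between is met within 5%.

What the phantoms do **not** emulate: physically rigorous photon
transport, PSF anisotropy, hemodynamics, motion, and the anatomical
layering of real cortex. Passing tests therefore demonstrate that the
pipeline removes the modeled degradations and recovers the modeled
geometry — not performance on in vivo data.

## Quality metrics

SBR = mean(signal)/mean(background) over annotated masks. MSE, and
PSNR = 10·log10(max(I)²/MSE). SSIM is scored per sliding uniform window
(default 11×11) as
`(2μuμv+Q1)(2σuv+Q2) / ((μu²+μv²+Q1)(σu²+σv²+Q2))`
with Q1 = Q2 = 0.01 applied exactly as stated (a compatibility flag
rescales them by the squared dynamic range as in the classic formulation,
which is how the implementation is cross-checked against scikit-image).
F1 = 2TP/(2TP+FP+FN) over voxel-wise confusion counts; the degenerate
empty-vs-empty case is defined as 1 with a warning.

## 3D morphometry

From a binary segmentation `A`, the skeleton `S` (Lee-type 3D
topology-preserving thinning) and surface `P` (vessel voxels with a
6-connected face-neighbor outside `A`; volume border counts as outside;
26-connectivity behind a flag) are derived. Five metrics are evaluated in
sliding cubic windows of side n (default 32, stride n/2; window sums via a
3D summed-area table, matched exactly against naive triple loops in
tests):

| metric | formula | meaning |
|---|---|---|
| VVD | ΣA / n³ | vessel volume density |
| VTI | ΣA / ΣS | thickness (diameter proxy); ≥ 1 |
| VSD | ΣS / n³ | skeleton (network) density |
| VCI | (ΣP)² / (4π ΣA) | morphological complexity |
| VSI | ΣP / n³ | surface-area (exchange) index |

Windows with ΣS = 0 (VTI) or ΣA = 0 (VCI) are *undefined*: flagged NaN and
excluded from profiles, dispersion, correlations and classifier features —
never imputed as zero. Depth profiles average defined windows per grid z;
dispersion is summarized as CV = std/mean per depth bin, the regional mean
CV (MCV), and the absolute MCV difference between adjacent regions (DMCV).
Metric independence is screened by Pearson correlation over co-defined
windows with |r| < 0.7 as the acceptance band.

Segmentation is automatic Otsu thresholding. Two named variants are
reconstructions (their exact definitions were open): *proportion-adjusted*
shifts the Otsu threshold until the foreground fraction enters a plausible
vessel-fraction band (default 1–20%); *weighted-optimal* sweeps candidate
thresholds maximizing normalized between-class variance minus a squared
penalty on the distance of the foreground fraction from that band. Both
log their thresholds; parameters are exposed.

## Region classification

Each fully defined window yields the feature vector
(VVD, VTI, VSD, VCI, VSI) with region labels 1 = neocortex, 2 = white
matter, 3 = hippocampus (0 = unclassified). Features are z-scored with
training statistics; linear decision hyperplanes `k·v + b` are fit with a
linear SVM (C = 1.0, exposed). The multi-class completion of the single
printed hyperplane is one-vs-rest with argmax of decision values
(one-vs-one voting available). Training operates on window-level vectors.
Models serialize to JSON and round-trip to 1e-12.

Region boundary depths are estimated from predicted label counts per depth
bin: a crossover is the first depth at which the count of one class
overtakes another (white matter over neocortex, hippocampus over white
matter), located by linear interpolation of the count difference between
bins.

## Numerical and testing choices

* All randomness flows through explicit integer seeds; child seeds are
  derived with `numpy.random.SeedSequence` and kept below 2³¹. Equal seeds
  and inputs give bit-identical outputs.
* Desk-scale test and acceptance runs use the identical code paths at
  reduced size: 32-px patches, T = 25, base width 8 with channel
  multipliers (1, 1, 2, 2), 64×64×32 phantom volumes. The architecture is
  resolution-relative, so nothing but scale changes.
* The diffusion training budget at desk scale (tens of epochs on a few
  hundred augmented patches) is set for CPU execution; loss histories are
  recorded per epoch and NaN losses abort with the epoch index.
* SSIM windowing, the Otsu variant definitions, the diffusion entry step
  and the inference normalization are the package's own documented
  completions of under-specified designs; each is configurable.

## Known limitations

* The stripe gate can fire on stripe-free frames with a dominant uniform
  background (DC rank-1 component); τ and `n_replace` are exposed for such
  data.
* The numpy U-Net trains at desk scale only; the package does not attempt
  GPU-scale 256-px/300-epoch training, although the configuration accepts
  it.
* VTI is a ratio proxy for diameter, not a distance-transform measurement;
  vessel-graph topology (branch statistics) is out of scope.
* The phantom's three-region classifier experiments use statistically
  distinct metric distributions per depth band, which is a deliberately
  idealized stand-in for anatomical region differences.
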