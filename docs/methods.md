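# Methods

## Problem setting

Probe-based confocal laser endomicroscopy (pCLE) images tissue through a
coherent fiber bundle: light is sampled only at the fiber cores, whose
transmission varies from fiber to fiber, so a hexagonal "honeycomb"
pattern is superimposed on the scene, on top of the usual acquisition
noise. Clean references do not exist for in-vivo acquisitions, and in
fluorescence microscopy they are expensive (hundreds of registered
exposures of a static field of view). `fbdenoise` implements a
single-image, self-supervised restoration pipeline for this regime: no
clean targets, no training corpus — each noisy image is its own training
set.

## The model

The observation model is `y = x + eps`, with `x` the latent clean image
and `eps` zero-mean noise, all intensities on the [0, 1] scale.

Three networks cooperate:

* **N-Net** — a fully convolutional noise-level estimator
  `sigma_y = F_E(y; W_E)`: 20 padded 3x3 convolutional layers of 64
  channels (defaults), ReLU between layers, no pooling and no batch
  normalisation, an absolute-value output transform so the per-pixel
  noise standard-deviation estimate is nonnegative and exactly the input
  shape.
* **D-Net** — a U-shaped denoiser `x_hat = F_D(y, sigma_y; W_D)`: depth 3
  with 64 first-layer channels (defaults), "same"-padded 3x3
  convolutions so skip connections concatenate without cropping, 2x2
  max-pool downsampling and bilinear 2x upsampling. The noisy image and
  the noise map enter concatenated as a 2-channel input; a config switch
  (`use_noise_map=False`) gives the 1-channel variant used in the
  ablation.
* **Q-Net** — a no-reference quality scorer with a hypernetwork-weighted
  head: a 6-conv backbone pools first and second activation moments from
  three scales into a 112-dim semantic vector; a hyper branch maps that
  vector to the weights and biases of the 4-layer fully connected
  quality head, which then scores the same vector. The head has no free
  parameters of its own — its weights are an output of the hyper branch,
  so scoring is content-conditioned.

### Blind-spot training

Training a denoiser against its own input collapses to the identity.
The masked self-supervised loss avoids this: each step hides a random
fraction of pixels (default 1%, desk-scale profile 5%), replacing each
with a uniformly drawn in-bounds neighbour from its 5x5 window (a
window-mean variant is available), and minimises

    L = mean_{i in M} ( F_D(y_masked, sigma)_i - y_i )^2

— the mean of squared errors *at masked positions only*. Because a
masked pixel's own value never reaches the network, the minimiser at
those pixels is the expected intensity given surrounding context
(J-invariance), which strips pixel-independent noise. The loss is a mean
rather than a sum so its scale, and hence the effective learning rate,
is independent of image size. A fresh mask is drawn every iteration from
a per-step seed derived from the run seed.

N-Net receives no supervision of its own: gradients reach it only
through D-Net's use of `sigma`. During training N-Net sees the masked
image (consistent with the loss); at checkpoint time both networks see
the unmasked observation. One Adam optimizer covers both parameter sets
at a constant learning rate (default 1e-4 per the full-scale recipe). An
optional smoothness penalty on `sigma` (squared forward differences,
weight 0 by default) is available for experimentation.

### Rise-then-fall and checkpoint selection

A convolutional network fitted to a single corrupted image reconstructs
structure before noise (the deep-image-prior effect), so restoration
quality along the run rises and then falls — and the peak iteration
differs per image. The loop therefore stores the restored image
`clip(F_D(y, F_E(y)), 0, 1)` every `save_every` steps (default every 100
of 3000). With a trained scorer, each checkpoint is scored, scores are
smoothed with a centred moving average (window 1 by default, 3 in the
desk-scale profile; partial windows at the edges), and the argmax —
earliest on ties — is returned. Without a scorer the last checkpoint is
returned.

### Q-Net training

The scorer is trained from scratch on pseudo-labelled synthetic
degradations of clean phantom bases — no pretrained weights anywhere.
Two sample families are combined:

1. **Pure noise series**: for each base and each classical noise model
   (additive Gaussian, Poisson photon noise, salt-and-pepper), six
   intensities on a geometric ladder; pseudo-score linear in the rank
   (rank 0 -> 100, max rank -> 0). Rank-based labels keep the families
   comparable although their intensity parameters live on different
   scales.
2. **Restoration-manifold grid**: checkpoints of a real run traverse a
   blur-noise trade-off (early: oversmoothed; late: noisy). The grid
   blurs each base at four levels and adds Gaussian noise at five
   levels; within a blur level the score falls linearly with noise rank,
   and the series ceiling falls by up to 60% with blur rank. Blur is
   deliberately scored as a milder defect than noise: an oversmoothed
   image still carries the scene.

Training minimises the L2 distance between the head output and
pseudo-score/100 (one Adam step per sample, reshuffled each epoch,
deterministic per seed); the returned scorer rescales by 100. Because a
single small scorer's content calibration is noisy, the standard recipe
(`train_checkpoint_scorer`) trains three members from different
initialisation seeds and averages their scores; ranking within a
trajectory — the only thing selection needs — is markedly more stable
for the ensemble than for any member. Images larger than 224x224 are
scored as the mean over five crops (corners + centre).

## Synthetic data

The simulator provides everything the pipeline consumes:

* **Phantoms** (`blobs`, `stripes`, `cells`): deterministic clean scenes
  with structure at several scales — smooth bumps, oriented bands with
  step edges, and soft-edged cell-like disks with darker interiors.
* **Fiber bundle**: cores on a hexagonal lattice (pitch in pixels), each
  a unit-peak Gaussian profile of scale `core_radius`, multiplied by the
  scene intensity at the core centre and a per-core transmission drawn
  with mean 1 and a configurable coefficient of variation, on a constant
  cladding background. This reproduces the defining artifact features —
  a spectral ring at spatial frequency 1/pitch and core-to-core
  brightness variability — without modelling optics (no cross-coupling,
  no per-fiber PSFs).
* **Noise models**: `gaussian` (std on the [0,1] scale), `poisson`
  (`y = Pois(x*lambda)/lambda`, one scalar controls severity),
  `salt_pepper` (each pixel set to 0 or 1 with probability p/2 each).
* **Stacks**: N independent noisy exposures of a static scene, per-frame
  seeds `seed + frame_index`. The frame average estimates the clean
  reference (RMSE follows sigma/sqrt(N)); the per-pixel sample standard
  deviation across frames is the ground-truth noise map, optionally
  normalised by its maximum (a stack whose std is at floating-point
  rounding level returns an all-zero map instead of amplifying noise).

What the simulator does *not* emulate: frame misregistration, detector
nonlinearity and fixed-pattern noise, spatial noise correlation, and
real tissue texture. Passing tests therefore demonstrate the mechanics
and the qualitative claims (denoising gain, rise-then-fall, scorer
monotonicity, ablation direction) on controlled synthetic scenes — not
clinical performance.

## Numerical core

No deep-learning framework is used; the networks run on a small
reverse-mode automatic-differentiation engine over float32 numpy arrays
(`fbdenoise._autodiff`). Convolutions are stride-1 zero-padded 3x3,
implemented as a patch-matrix multiply with channel-major layout;
backward passes are the standard transposed forms (input gradients via
correlation with flipped kernels). Bilinear upsampling uses the
area-preserving convention (output centres at `(o+0.5)/2 - 0.5`, border
clamped) with an exact adjoint for the backward pass. Max-pool backward
routes the gradient to the first argmax. Every operator's gradient is
verified against central finite differences in the test suite. Adam
uses the standard bias-corrected moments.

## Parameters that matter

| parameter | default | desk-scale | meaning |
|---|---|---|---|
| `TrainConfig.iterations` | 3000 | 1500 | optimisation steps per image |
| `TrainConfig.save_every` | 100 | 100 | checkpoint interval (steps) |
| `TrainConfig.learning_rate` | 1e-4 | 1e-2 | Adam step size |
| `mask.fraction` | 0.01 | 0.05 | pixels hidden per step |
| `mask.window` | 5 | 5 | replacement neighbourhood (px) |
| `smoothing_window` | 1 | 3 | checkpoint-score smoothing |
| N-Net layers x channels | 20 x 64 | 3 x 6 | noise estimator capacity |
| D-Net depth x channels | 3 x 64 | 2 x 6 | denoiser capacity |

The desk-scale profile (`desk_scale_configs`,
`desk_scale_train_config`) is the package's CPU-sized study condition:
128x128 images, narrow networks, a larger step and mask fraction so a
single run traverses the full rise-then-fall trajectory in roughly a
minute on one core. The full-scale defaults follow the per-image recipe
the method was designed with (512x512, 3000 iterations).

## Design choices where the design was open

* **D-Net activation** is LeakyReLU(0.1) by default (plain ReLU is a
  config option). At desk-scale widths, all-ReLU U-Nets occasionally die
  wholesale (constant output) on smooth scenes; the leaky slope removes
  that failure mode and is otherwise inconsequential.
* **Ablation semantics**: disabling the noise estimator feeds an
  all-zero map to the unchanged 2-channel D-Net, so both arms share
  weight initialisation and mask sequence and the toggle isolates
  N-Net's contribution exactly. The true 1-channel D-Net remains
  available via `use_noise_map=False`.
* **No weight sharing** between N-Net and D-Net; they only share the
  optimizer and the loss.
* **Masked image to N-Net during training**, unmasked at checkpoint
  time.
* **Odd-sized inputs** are reflect-padded to the next multiple of
  `2^depth` inside D-Net and cropped back after.
* **"Pepper" noise** is implemented as standard salt-and-pepper impulse
  noise.
* **Noise-map normalisation** divides by the per-image maximum; the
  unnormalised map is always available.
* **PSNR cap**: identical images report 100 dB (finite, serializable);
  SSIM uses the standard 7-pixel window and stabilizers for unit range.
* **Checkpoints store images, not weights**, keeping runs small.

## Known limitations

* Blind-spot losses assume pixel-independent noise; structured noise
  (e.g. correlated honeycomb residuals, row artifacts) violates the
  assumption and is not addressed.
* The scorer is trained on synthetic degradations of synthetic phantoms;
  nothing here calibrates it to human opinion or to real microscopy
  texture.
* The Q-Net `resnet50` backbone option requires externally supplied
  weights and is not constructible in this package.
* Per-image optimisation is inherently slow compared to amortised
  feed-forward denoisers; the method trades runtime for zero training
  data.
* Because the blind-spot loss by construction resists fitting the
  noise, the post-peak quality decline is shallower than in
  reconstruction-loss (deep-image-prior) training, and its onset varies
  with content and seed; in short desk-scale runs the PSNR peak can fall
  near the end of the checkpoint window. Longer schedules give the
  rise-then-fall trend more room.
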