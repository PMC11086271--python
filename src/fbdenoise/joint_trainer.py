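"""Per-image joint optimisation of the noise estimator and the denoiser.

The method is single-image and self-supervised, in the deep-image-prior
family: for one noisy observation ``y`` the loop repeatedly

1. draws a fresh blind-spot mask and builds the masked image;
2. runs N-Net on the masked image to estimate the noise level map
   ``sigma`` (or uses an all-zero map when the N-Net arm is ablated);
3. runs D-Net on (masked image, sigma) and takes one Adam step on the
   masked self-supervised loss against the original noisy values;
4. on a fixed schedule, stores the restoration D-Net(y, N-Net(y))
   clipped to [0,1] as a checkpoint image.

Restoration quality along the checkpoint trajectory rises while the
network learns image structure and falls once it begins to fit the
noise, so if a trained quality scorer is supplied the checkpoint with
the best (smoothed) score is returned; otherwise the last one.

A single Adam instance covers N-Net and D-Net parameters jointly with a
constant learning rate.  Everything is deterministic under the config
seed: network initialisations and the mask sequence depend only on it,
so an ablation pair (with/without N-Net) sees identical D-Net weights
and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .masking import apply_mask, make_mask
from .metrics_io import psnr
from .models import DNet, DNetConfig, NNet, NNetConfig
from .qnet import ScoreTrajectory, score_trajectory, select_best
from .simulate import validate_image

__all__ = [
    "MaskConfig",
    "TrainConfig",
    "CheckpointTrajectory",
    "denoise_single",
    "run_ablation",
    "psnr_trajectory",
    "desk_scale_configs",
    "desk_scale_train_config",
]


@dataclass
class MaskConfig:
    fraction: float = 0.01
    replacement: str = "random_neighbor"
    window: int = 5


@dataclass
class TrainConfig:
    """Optimisation schedule for one single-image run."""

    iterations: int = 3000
    save_every: int = 100
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    use_nnet: bool = True
    seed: int = 0
    mask: MaskConfig = field(default_factory=MaskConfig)
    smoothing_window: int = 1      # checkpoint-score smoothing for selection
    tv_weight: float = 0.0         # optional roughness penalty on sigma

    def validate(self):
        if self.iterations < self.save_every or self.iterations < 1:
            raise ValueError("iterations must be >= save_every >= 1")
        if self.save_every < 1 or self.iterations % self.save_every:
            raise ValueError("save_every must divide iterations")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class CheckpointTrajectory:
    """Restored images stored on the checkpoint schedule."""

    iterations: list
    images: list
    scores: list | None = None
    selected: int | None = None

    def as_score_trajectory(self):
        return ScoreTrajectory(iterations=list(self.iterations),
                               scores=list(self.scores))


def desk_scale_configs():
    """Reduced-width model configs for CPU-scale single-image runs.

    Narrow variants of the default architectures (3-layer/6-channel
    N-Net, depth-2/6-channel U-Net) that keep a 1500-iteration run on a
    128x128 image around a minute on one CPU core while preserving every
    structural property of the full-width models.
    """
    return (NNetConfig(n_layers=3, channels=6),
            DNetConfig(depth=2, first_channels=6))


def desk_scale_train_config(seed=0):
    """The reduced-scale training schedule that pairs with
    :func:`desk_scale_configs`.

    1500 iterations saved every 100; a larger step (1e-2) and mask
    fraction (0.05) than the full-scale defaults, so the narrow networks
    traverse the whole rise-then-fall restoration trajectory within the
    run; checkpoint scores smoothed over 3 checkpoints before selection.
    """
    return TrainConfig(iterations=1500, save_every=100, learning_rate=1e-2,
                       seed=seed, mask=MaskConfig(fraction=0.05),
                       smoothing_window=3)


def denoise_single(noisy, config: TrainConfig, scorer=None,
                   nnet_config=None, dnet_config=None):
    """Denoise one image by joint self-supervised training.

    Returns ``(denoised, trajectory, noise_map)``: the selected
    restoration, the full checkpoint trajectory, and the estimated
    noise level map at the selected checkpoint (all-zero when
    ``config.use_nnet`` is false).
    """
    noisy = validate_image(noisy, "noisy").astype(np.float32)
    config.validate()
    h, w = noisy.shape
    base = int(config.seed)

    # D-Net init is independent of use_nnet so ablation arms share it
    dnet = DNet(dnet_config or DNetConfig(), seed=base + 23)
    nnet = NNet(nnet_config or NNetConfig(), seed=base + 11)
    params = list(dnet.params())
    if config.use_nnet:
        params += nnet.params()
    opt = ad.Adam(params, lr=config.learning_rate)

    zero_map = np.zeros((1, h, w), dtype=np.float32)
    target_all = noisy.astype(np.float64)

    ckpt_iters, ckpt_images, ckpt_sigmas = [], [], []
    for step in range(1, config.iterations + 1):
        mask = make_mask(noisy, mask_fraction=config.mask.fraction,
                         replacement=config.mask.replacement,
                         window=config.mask.window, seed=[base, step])
        y_m = apply_mask(noisy, mask).astype(np.float32)

        opt.zero_grad()
        x_in = ad.constant(y_m[None])
        sigma = nnet(x_in) if config.use_nnet else ad.constant(zero_map)
        pred = dnet(x_in, sigma)
        picked = ad.gather_pixels(pred, mask.rows, mask.cols)
        loss = ad.mse_to(picked, target_all[mask.rows, mask.cols])
        if config.tv_weight > 0 and config.use_nnet:
            loss = ad.add(loss, ad.scale(ad.tv2d(sigma), config.tv_weight))
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"non-finite loss at step {step}")
        ad.backward(loss)
        opt.step()

        if step % config.save_every == 0:
            y_t = ad.constant(noisy[None])
            sig_eval = nnet(y_t) if config.use_nnet else ad.constant(zero_map)
            restored = dnet(y_t, sig_eval)
            ckpt_iters.append(step)
            ckpt_images.append(np.clip(restored.data[0], 0.0, 1.0).astype(np.float64))
            ckpt_sigmas.append(sig_eval.data[0].astype(np.float64))

    traj = CheckpointTrajectory(iterations=ckpt_iters, images=ckpt_images)
    if scorer is not None:
        st = score_trajectory(scorer, ckpt_images, ckpt_iters)
        traj.scores = st.scores
        traj.selected = select_best(st, config.smoothing_window)
    else:
        traj.selected = len(ckpt_images) - 1
    return ckpt_images[traj.selected], traj, ckpt_sigmas[traj.selected]


def run_ablation(noisy, config: TrainConfig, scorer=None,
                 nnet_config=None, dnet_config=None):
    """Run the with/without-N-Net pair under identical seeds and masks.

    Only ``use_nnet`` differs between the arms; D-Net initialisation
    and the mask sequence are shared through the config seed.  Returns
    ``(with_nnet_result, without_nnet_result)``, each a
    ``(denoised, trajectory, noise_map)`` triple.
    """
    from dataclasses import replace

    cfg_with = replace(config, use_nnet=True)
    cfg_without = replace(config, use_nnet=False)
    res_with = denoise_single(noisy, cfg_with, scorer, nnet_config, dnet_config)
    res_without = denoise_single(noisy, cfg_without, scorer, nnet_config, dnet_config)
    return res_with, res_without


def psnr_trajectory(trajectory: CheckpointTrajectory, clean):
    """PSNR of every checkpoint against the (simulation) ground truth."""
    clean = np.asarray(clean, dtype=np.float64)
    if clean.shape != np.asarray(trajectory.images[0]).shape:
        raise ValueError("clean shape differs from checkpoint shape")
    return [psnr(img, clean) for img in trajectory.images]
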