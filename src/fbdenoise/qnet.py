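"""Training and application of the no-reference quality scorer.

The scorer (Q-Net, :class:`fbdenoise.models.QNet`) is trained from
scratch on pseudo-labelled synthetic degradations: each clean base image
is corrupted at a ladder of geometrically increasing intensities under
each of the three classical noise models, and the target quality score
is a fixed monotone map of the intensity *rank* (rank 0 -> 100, max rank
-> 0, linear in rank).  Ranking by rank rather than raw intensity keeps
the pseudo-labels comparable across noise kinds, whose intensity
parameters live on different scales.

A trained scorer is then used to score the checkpoint images of a
restoration run: restoration quality rises while the network learns
image structure and falls once it starts fitting noise, so the
checkpoint with the maximal (optionally smoothed) score is selected as
the final output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .models import QNet, QNetConfig
from .metrics_io import gaussian_reference
from .simulate import NOISE_KINDS, NoiseModelSpec, add_noise

__all__ = [
    "DegradedSample",
    "ScoreTrajectory",
    "make_qnet_training_set",
    "train_qnet",
    "score_trajectory",
    "select_best",
    "intensity_ladder",
    "TRAINING_KINDS",
    "make_restoration_training_set",
    "EnsembleScorer",
    "train_checkpoint_scorer",
]

# intensity ladders: geometric from mild to severe degradation.  For the
# Poisson model "intensity" is the photon count lambda, where FEWER
# photons mean MORE noise, so the ladder descends.  "blur" (Gaussian
# low-pass sigma in pixels) is not a noise model but an extra training
# family: checkpoint selection must rank oversmoothed restorations below
# well-restored ones, so the scorer has to see loss of detail as a
# degradation too.
_LADDERS = {
    "gaussian": (0.02, 0.5, "asc"),
    "poisson": (2000.0, 8.0, "desc"),
    "salt_pepper": (0.01, 0.5, "asc"),
    "blur": (0.5, 4.0, "asc"),
}

TRAINING_KINDS = ("gaussian", "poisson", "salt_pepper", "blur")


def intensity_ladder(kind, n_levels):
    """Geometric degradation ladder for one noise kind, mild -> severe."""
    lo, hi, _ = _LADDERS[kind]
    return np.geomspace(lo, hi, n_levels)


@dataclass
class DegradedSample:
    image: np.ndarray
    noise_kind: str
    intensity_rank: int
    pseudo_score: float
    base_id: int = 0


@dataclass
class ScoreTrajectory:
    iterations: list
    scores: list

    def __post_init__(self):
        if len(self.iterations) != len(self.scores):
            raise ValueError("iterations and scores must have equal length")
        if len(self.iterations) == 0:
            raise ValueError("empty trajectory")
        if any(b <= a for a, b in zip(self.iterations, self.iterations[1:])):
            raise ValueError("iterations must be strictly increasing")


def make_qnet_training_set(bases, kinds=TRAINING_KINDS, n_levels=6, seed=0):
    """Pseudo-labelled degradation series for Q-Net training.

    For every base image and degradation kind, ``n_levels`` images are
    generated at geometrically increasing degradation.  Pseudo-scores
    are linear in rank: rank 0 scores 100, the maximal rank scores 0,
    so scores strictly decrease with degradation within every series.
    ``kinds`` defaults to the three classical noise families plus a
    Gaussian-blur family (see :data:`TRAINING_KINDS`).
    """
    bases = list(bases)
    if not bases:
        raise ValueError("no base images given")
    if n_levels < 3:
        raise ValueError("need at least 3 degradation levels")
    samples = []
    s = int(seed)
    for bi, base in enumerate(bases):
        for kind in kinds:
            ladder = intensity_ladder(kind, n_levels)
            for rank, intensity in enumerate(ladder):
                if kind == "blur":
                    img = gaussian_reference(base, float(intensity))
                else:
                    img = add_noise(base, NoiseModelSpec(kind, float(intensity),
                                                         seed=s))
                s += 1
                samples.append(DegradedSample(
                    image=img, noise_kind=kind, intensity_rank=rank,
                    pseudo_score=100.0 * (1.0 - rank / (n_levels - 1)),
                    base_id=bi))
    return samples


def train_qnet(samples, config: QNetConfig | None = None, epochs=30,
               seed=0, learning_rate=1e-3):
    """Fit Q-Net by L2 regression of its score onto the pseudo-scores.

    One Adam step per sample, samples reshuffled every epoch;
    deterministic under a fixed seed.  Internally the regression target
    is pseudo_score/100 and the returned scorer rescales by 100, so the
    optimisation runs at unit scale.  ``epochs=0`` returns the
    untrained (finite-scoring) initialisation.
    """
    samples = list(samples)
    series = {(s.base_id, s.noise_kind) for s in samples}
    if len(series) < 2:
        raise ValueError("need at least two degradation series")
    net = QNet(config, seed=seed)
    opt = ad.Adam(net.params(), lr=learning_rate)
    rng = np.random.default_rng(seed)
    order = np.arange(len(samples))
    for epoch in range(epochs):
        rng.shuffle(order)
        for i in order:
            s = samples[i]
            opt.zero_grad()
            score = net.score_tensor(s.image.astype(np.float32))
            loss = ad.mse_to(score, np.array([s.pseudo_score / 100.0],
                                             dtype=np.float32))
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"Q-Net training diverged at epoch {epoch}, sample {i}")
            ad.backward(loss)
            opt.step()
    net.score_scale = 100.0
    return net


def make_restoration_training_set(bases, seed=0, blurs=(0.0, 0.6, 1.2, 2.4),
                                  noises=(0.0, 0.02, 0.05, 0.1, 0.2),
                                  blur_penalty=0.6):
    """Degradation samples on the blur x noise manifold of restorations.

    Checkpoints of a single-image run traverse a two-parameter family:
    early restorations are oversmoothed, late ones carry residual noise.
    This builder produces that manifold explicitly: every base image is
    blurred at each level in ``blurs`` and then corrupted with additive
    Gaussian noise at each level in ``noises``.  Within one blur level
    the pseudo-score falls linearly with the noise rank; across blur
    levels the series ceiling falls by up to ``blur_penalty`` (blur is
    scored as a milder defect than noise, since an oversmoothed image
    still carries the scene's structure).
    """
    bases = list(bases)
    if not bases:
        raise ValueError("no base images given")
    samples = []
    s = int(seed)
    for bi, base in enumerate(bases):
        for br, sb in enumerate(blurs):
            blurred = gaussian_reference(base, float(sb)) if sb > 0 else base
            ceiling = 100.0 * (1.0 - blur_penalty * br / (len(blurs) - 1))
            for nr, sn in enumerate(noises):
                if sn == 0:
                    img = blurred
                else:
                    rng = np.random.default_rng(s)
                    img = np.clip(blurred + rng.normal(0, sn, base.shape), 0, 1)
                s += 1
                samples.append(DegradedSample(
                    image=img, noise_kind=f"blurred_level_{br}",
                    intensity_rank=nr,
                    pseudo_score=ceiling * (1.0 - nr / (len(noises) - 1)),
                    base_id=bi))
    return samples


class EnsembleScorer:
    """Mean score of independently initialised Q-Net members.

    Averaging decorrelates the members' content-calibration errors, so
    within-trajectory rankings are markedly more stable than any single
    member's.
    """

    def __init__(self, members):
        if not members:
            raise ValueError("empty ensemble")
        self.members = list(members)

    def __call__(self, image):
        return float(np.mean([m(image) for m in self.members]))


def train_checkpoint_scorer(bases, seed=0, epochs=25, n_members=3,
                            config=None, learning_rate=1e-3):
    """The standard scorer recipe used by the denoising pipeline.

    Trains ``n_members`` Q-Nets (different init/shuffle seeds) on the
    union of the pure noise-family series
    (:func:`make_qnet_training_set` with the three classical noise
    models) and the blur x noise restoration manifold
    (:func:`make_restoration_training_set`), and returns their
    :class:`EnsembleScorer`.
    """
    bases = list(bases)
    samples = (make_qnet_training_set(bases, kinds=NOISE_KINDS, n_levels=6,
                                      seed=seed)
               + make_restoration_training_set(bases, seed=seed + 5000))
    members = [train_qnet(samples, config=config, epochs=epochs,
                          seed=seed + 100 * m, learning_rate=learning_rate)
               for m in range(n_members)]
    return EnsembleScorer(members)


def score_trajectory(scorer, checkpoints, iterations):
    """Score every checkpoint image, preserving order."""
    checkpoints = list(checkpoints)
    iterations = list(iterations)
    if not checkpoints:
        raise ValueError("no checkpoints to score")
    if len(checkpoints) != len(iterations):
        raise ValueError("checkpoints and iterations must have equal length")
    return ScoreTrajectory(iterations=iterations,
                           scores=[scorer(img) for img in checkpoints])


def _moving_average(values, window):
    """Centred moving average with partial windows at the edges."""
    values = np.asarray(values, dtype=np.float64)
    half = window // 2
    out = np.empty_like(values)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def select_best(trajectory: ScoreTrajectory, smoothing_window=1):
    """Index of the checkpoint with the maximal smoothed score.

    Ties break toward the earlier checkpoint.  Returns the position in
    the trajectory; the corresponding iteration number is
    ``trajectory.iterations[index]``.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    smoothed = _moving_average(trajectory.scores, smoothing_window)
    return int(np.argmax(smoothed))
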