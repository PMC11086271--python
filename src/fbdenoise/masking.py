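"""Blind-spot masking and the masked self-supervised loss.

A denoiser trained to reproduce its own input learns the identity map.
Blind-spot training prevents this: a small random subset of pixels is
hidden (replaced with values drawn from their neighbourhood), the
network predicts the full image from the masked input, and the loss is
evaluated *only at the hidden positions* against the original noisy
values.  Since a masked pixel's own value never reaches the network,
the minimiser is the expected clean intensity given the surrounding
context (J-invariance), not the noise realisation.

The loss here is the mean (not the sum) of squared errors over the
masked positions, which makes its scale independent of image size at a
fixed mask fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["BlindSpotMask", "make_mask", "apply_mask", "masked_loss"]

REPLACEMENT_STRATEGIES = ("random_neighbor", "local_mean")


@dataclass
class BlindSpotMask:
    """Masked-pixel coordinates and their replacement values for one step."""

    rows: np.ndarray            # (n,) row indices
    cols: np.ndarray            # (n,) col indices
    replacements: np.ndarray    # (n,) replacement intensities
    shape: tuple                # (H, W) of the image the mask was built for
    mask_fraction: float

    @property
    def n_masked(self):
        return len(self.rows)


def make_mask(image, mask_fraction=0.01, replacement="random_neighbor",
              window=5, seed=0):
    """Draw a fresh blind-spot mask for ``image``.

    ``round(mask_fraction * H * W)`` distinct positions are sampled
    uniformly without replacement.  Each masked pixel's replacement is
    drawn from the ``window`` x ``window`` neighbourhood around it,
    excluding the centre pixel itself: either one neighbour chosen
    uniformly (``random_neighbor``) or the neighbourhood mean
    (``local_mean``).  Out-of-bounds window positions are ignored.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    h, w = image.shape
    if not 0.0 < mask_fraction <= 0.5:
        raise ValueError("mask_fraction must lie in (0, 0.5]")
    if replacement not in REPLACEMENT_STRATEGIES:
        raise ValueError(f"unknown replacement strategy {replacement!r}")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(h, w):
        raise ValueError("window larger than image")

    n = max(1, int(round(mask_fraction * h * w)))
    rng = np.random.default_rng(seed)
    flat = rng.choice(h * w, size=n, replace=False)
    rows, cols = np.divmod(flat, w)

    half = window // 2
    if replacement == "local_mean":
        # window mean excluding the centre, with partial windows at the
        # borders: box-filter sums divided by in-bounds counts minus one
        sums = ndimage.uniform_filter(image, window, mode="constant") * window ** 2
        counts = ndimage.uniform_filter(np.ones_like(image), window,
                                        mode="constant") * window ** 2
        mean_excl = (sums - image) / (np.round(counts) - 1)
        reps = mean_excl[rows, cols]
    else:
        # one in-bounds neighbour per masked pixel, uniform over the
        # window minus its centre, by vectorised rejection sampling
        rr = np.empty(n, dtype=np.int64)
        cc = np.empty(n, dtype=np.int64)
        todo = np.arange(n)
        while todo.size:
            dr = rng.integers(-half, half + 1, size=todo.size)
            dc = rng.integers(-half, half + 1, size=todo.size)
            nr, nc = rows[todo] + dr, cols[todo] + dc
            ok = ((dr != 0) | (dc != 0)) & (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
            rr[todo[ok]] = nr[ok]
            cc[todo[ok]] = nc[ok]
            todo = todo[~ok]
        reps = image[rr, cc]
    return BlindSpotMask(rows=rows, cols=cols, replacements=reps,
                         shape=(h, w), mask_fraction=mask_fraction)


def apply_mask(image, mask: BlindSpotMask):
    """Write the replacement values into a copy of ``image``."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != mask.shape:
        raise ValueError("mask was built for a different image shape")
    out = image.copy()
    out[mask.rows, mask.cols] = mask.replacements
    return out


def masked_loss(prediction, original, mask: BlindSpotMask):
    """Mean squared error restricted to the masked positions.

    Zero iff the prediction matches the original at every masked pixel;
    values at unmasked positions never influence the result.
    """
    prediction = np.asarray(prediction, dtype=np.float64)
    original = np.asarray(original, dtype=np.float64)
    if prediction.shape != original.shape:
        raise ValueError("prediction and original shapes differ")
    if prediction.shape != mask.shape:
        raise ValueError("mask was built for a different image shape")
    if mask.n_masked == 0:
        raise ValueError("empty mask")
    d = prediction[mask.rows, mask.cols] - original[mask.rows, mask.cols]
    return float(np.mean(d * d))
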