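"""Synthetic data generation.

Everything the pipeline consumes can be simulated here with no external
downloads:

* clean grayscale phantoms with structure at several spatial scales
  (:func:`make_phantom`);
* pCLE-like images where a honeycomb fiber-bundle pattern is
  superimposed on the underlying scene (:func:`apply_fiber_bundle`) --
  light reaches the detector only at fiber-core sites on a hexagonal
  lattice, and per-core transmission varies from fiber to fiber;
* noisy observations under three classical noise models -- additive
  Gaussian, Poisson (photon-count) and salt-and-pepper impulse noise
  (:func:`add_noise`);
* multi-frame stacks of a static scene, from which a clean reference is
  formed by frame averaging and a ground-truth noise map by the
  per-pixel standard deviation across frames
  (:func:`make_stack` / :func:`average_stack` /
  :func:`noise_map_from_stack`) -- the construction used by fluorescence
  benchmarks that average 400 registered shots per field of view.

All operations are bitwise-deterministic for a fixed seed.  Images are
float arrays in [0, 1]; stacks derive per-frame seeds as
``seed + frame_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameStack",
    "NoiseModelSpec",
    "BundleSpec",
    "make_phantom",
    "apply_fiber_bundle",
    "add_noise",
    "make_stack",
    "average_stack",
    "noise_map_from_stack",
    "hex_core_centers",
    "validate_image",
]

MIN_SIZE = 16

NOISE_KINDS = ("gaussian", "poisson", "salt_pepper")
PHANTOM_KINDS = ("blobs", "stripes", "cells")


def validate_image(image, name="image"):
    """Check an ImageGrid contract: 2-D, finite, in [0,1], >= 16 px a side."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
        raise ValueError(f"{name} must be at least {MIN_SIZE}x{MIN_SIZE}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return arr


@dataclass
class NoiseModelSpec:
    """One of the three classical noise models.

    ``intensity`` means: gaussian -- noise std on the [0,1] scale;
    poisson -- the photon-count scaling lambda_max (y = Pois(x*lam)/lam);
    salt_pepper -- the corruption probability (half salt, half pepper).
    """

    kind: str
    intensity: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")
        if self.kind == "salt_pepper" and self.intensity > 1:
            raise ValueError("salt_pepper intensity is a probability <= 1")


@dataclass
class BundleSpec:
    """Geometry and statistics of the simulated fiber bundle."""

    core_pitch: float = 6.0         # pixels between adjacent core centers
    core_radius: float = 1.5        # Gaussian core profile scale (pixels)
    transmission_cv: float = 0.15   # coefficient of variation of transmission
    cladding_level: float = 0.05    # background intensity in [0,1]
    seed: int = 0

    def __post_init__(self):
        if self.core_pitch <= 0 or self.core_radius <= 0:
            raise ValueError("core_pitch and core_radius must be positive")
        if self.transmission_cv < 0:
            raise ValueError("transmission_cv must be nonnegative")
        if not 0.0 <= self.cladding_level <= 1.0:
            raise ValueError("cladding_level must lie in [0, 1]")


@dataclass
class FrameStack:
    """N registered noisy frames of one static scene.

    ``frames`` is an (N, H, W) array; ``scene`` the underlying clean
    image (known only in simulation).
    """

    frames: np.ndarray
    scene: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("a stack needs >= 2 frames of equal shape")
        if self.scene is not None:
            self.scene = np.asarray(self.scene, dtype=np.float64)
            if self.scene.shape != self.frames.shape[1:]:
                raise ValueError("scene shape differs from frame shape")

    @property
    def n_frames(self):
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# phantoms


def _normalize01(img):
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def make_phantom(height, width, kind="cells", seed=0):
    """Deterministic clean test scene with multi-scale structure.

    ``blobs``   -- smooth sum of random Gaussian bumps;
    ``stripes`` -- oriented sinusoidal bands over a smooth gradient,
                   thresholded in places to create edges;
    ``cells``   -- bright disks with darker interiors (membrane-like
                   rings) on a dim, slowly varying background.
    """
    if height < MIN_SIZE or width < MIN_SIZE:
        raise ValueError(f"phantom must be at least {MIN_SIZE}x{MIN_SIZE}")
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)

    if kind == "blobs":
        img = np.zeros((height, width))
        n = max(4, (height * width) // 400)
        for _ in range(n):
            cy, cx = rng.uniform(0, height), rng.uniform(0, width)
            s = rng.uniform(0.02, 0.12) * min(height, width)
            a = rng.uniform(0.3, 1.0)
            img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
        return _normalize01(img)

    if kind == "stripes":
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(3.0, 6.0) / min(height, width)
        phase = rng.uniform(0, 2 * np.pi)
        u = np.cos(theta) * xx + np.sin(theta) * yy
        img = 0.5 + 0.35 * np.sin(2 * np.pi * freq * u + phase)
        # hard-edge band: threshold one diagonal half to add step edges
        band = np.cos(theta + np.pi / 3) * xx + np.sin(theta + np.pi / 3) * yy
        mask = (band % (0.25 * min(height, width))) < (0.1 * min(height, width))
        img = np.where(mask, (img > 0.5).astype(np.float64), img)
        img += 0.1 * (xx / width)  # smooth gradient
        return _normalize01(img)

    # cells
    img = 0.08 + 0.06 * np.sin(2 * np.pi * xx / width) * np.cos(2 * np.pi * yy / height)
    n = max(3, (height * width) // 900)
    for _ in range(n):
        cy, cx = rng.uniform(0, height), rng.uniform(0, width)
        r = rng.uniform(0.05, 0.14) * min(height, width)
        a = rng.uniform(0.5, 1.0)
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        disk = a / (1.0 + np.exp((d - r) / 1.0))         # soft-edged disk
        interior = 0.45 * a / (1.0 + np.exp((d - 0.6 * r) / 1.0))
        img = np.maximum(img, disk - interior)
    return np.clip(_normalize01(img), 0.0, 1.0)


# ---------------------------------------------------------------------------
# fiber bundle


def hex_core_centers(height, width, pitch):
    """Fiber-core centers on a hexagonal lattice covering the image.

    Rows are spaced ``pitch * sqrt(3)/2`` apart; odd rows are offset by
    half a pitch.  Returns an (n, 2) float array of (row, col) centers.
    """
    dy = pitch * np.sqrt(3.0) / 2.0
    centers = []
    r = 0
    y = 0.0
    while y < height:
        x0 = (pitch / 2.0) if (r % 2) else 0.0
        x = x0
        while x < width:
            centers.append((y, x))
            x += pitch
        y += dy
        r += 1
    return np.array(centers)


def apply_fiber_bundle(scene, spec: BundleSpec):
    """Superimpose the honeycomb fiber-bundle sampling pattern on a scene.

    The output is ``cladding_level + sum_c t_c * scene(center_c) * G_c``,
    where cores sit on a hexagonal lattice with the given pitch, ``G_c``
    is a unit-peak Gaussian of scale ``core_radius`` centered on core c,
    and per-core transmissions ``t_c`` have mean 1 and coefficient of
    variation ``transmission_cv``.  Clipped to [0, 1].
    """
    scene = validate_image(scene, "scene")
    h, w = scene.shape
    rng = np.random.default_rng(spec.seed)
    centers = hex_core_centers(h, w, spec.core_pitch)
    if spec.transmission_cv > 0:
        t = rng.normal(1.0, spec.transmission_cv, size=len(centers))
        t = np.clip(t, 0.0, None)
    else:
        t = np.ones(len(centers))

    # deposit per-core amplitude at the (rounded) center pixel, then blur
    # with a Gaussian and rescale to unit peak: exact for non-overlapping
    # cores, a good approximation when tails overlap.
    amp = np.zeros((h, w))
    ci = np.clip(np.round(centers[:, 0]).astype(int), 0, h - 1)
    cj = np.clip(np.round(centers[:, 1]).astype(int), 0, w - 1)
    vals = t * scene[ci, cj]
    np.add.at(amp, (ci, cj), vals)
    sig = spec.core_radius
    out = ndimage.gaussian_filter(amp, sig, mode="constant") * (2.0 * np.pi * sig * sig)
    return np.clip(spec.cladding_level + out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# noise models


def add_noise(clean, spec: NoiseModelSpec):
    """One noisy observation of ``clean`` under the given noise model."""
    clean = validate_image(clean, "clean")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian":
        if spec.intensity == 0:
            return clean.copy()
        return np.clip(clean + rng.normal(0.0, spec.intensity, clean.shape), 0.0, 1.0)
    if spec.kind == "poisson":
        if spec.intensity == 0:
            return clean.copy()
        lam = spec.intensity
        return np.clip(rng.poisson(clean * lam) / lam, 0.0, 1.0)
    # salt_pepper
    u = rng.random(clean.shape)
    out = clean.copy()
    out[u < spec.intensity / 2.0] = 0.0
    out[(u >= spec.intensity / 2.0) & (u < spec.intensity)] = 1.0
    return out


def make_stack(scene, spec: NoiseModelSpec, n_frames):
    """``n_frames`` independent noisy shots of one static scene.

    Frame i uses seed ``spec.seed + i`` so the stack is reproducible
    while frames stay independent.
    """
    if n_frames < 2:
        raise ValueError("a stack needs at least 2 frames")
    scene = validate_image(scene, "scene")
    frames = np.stack([
        add_noise(scene, NoiseModelSpec(spec.kind, spec.intensity, spec.seed + i))
        for i in range(n_frames)
    ])
    return FrameStack(frames=frames, scene=scene)


def average_stack(stack: FrameStack):
    """Per-pixel mean of the frames: the clean reference estimate."""
    return stack.frames.mean(axis=0)


def noise_map_from_stack(stack: FrameStack, normalize=False):
    """Per-pixel sample standard deviation across frames.

    With ``normalize=True`` the map is divided by its maximum so values
    lie in [0, 1]; an all-identical (zero-variance) stack returns an
    all-zero map in either mode.
    """
    sd = stack.frames.std(axis=0, ddof=1)
    if normalize:
        mx = sd.max()
        # guard against an (effectively) constant stack, where the map is
        # pure floating-point rounding noise
        if mx > 1e-9:
            sd = sd / mx
        else:
            sd = np.zeros_like(sd)
    return sd
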