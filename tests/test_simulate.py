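"""Synthetic-data subsystem: phantoms, fiber bundle, noise models, stacks."""

import numpy as np
import pytest

from fbdenoise import simulate as sim


# ---------------------------------------------------------------------------
# phantoms


@pytest.mark.parametrize("kind", sim.PHANTOM_KINDS)
def test_phantom_deterministic_and_in_range(kind):
    a = sim.make_phantom(64, 64, kind, seed=1)
    b = sim.make_phantom(64, 64, kind, seed=1)
    np.testing.assert_array_equal(a, b)
    assert a.min() >= 0.0 and a.max() <= 1.0
    assert sim.make_phantom(128, 128, kind, seed=7).var() > 0


def test_phantom_rejects_small_dimensions():
    with pytest.raises(ValueError):
        sim.make_phantom(8, 64, "blobs", seed=0)
    with pytest.raises(ValueError):
        sim.make_phantom(64, 64, "nonsense", seed=0)


# ---------------------------------------------------------------------------
# fiber bundle


def test_bundle_zero_variability_gives_equal_core_peaks():
    scene = np.ones((64, 64))
    spec = sim.BundleSpec(core_pitch=8.0, core_radius=1.2, transmission_cv=0.0,
                          cladding_level=0.0, seed=0)
    out = sim.apply_fiber_bundle(scene, spec)
    centers = sim.hex_core_centers(64, 64, 8.0)
    ci = np.round(centers[:, 0]).astype(int)
    cj = np.round(centers[:, 1]).astype(int)
    interior = (ci > 4) & (ci < 60) & (cj > 4) & (cj < 60)
    peaks = out[ci[interior], cj[interior]]
    assert peaks.std() < 1e-6 * max(1.0, peaks.mean())


def test_bundle_deterministic_and_validates():
    scene = sim.make_phantom(64, 64, "blobs", seed=3)
    spec = sim.BundleSpec(seed=5)
    np.testing.assert_array_equal(sim.apply_fiber_bundle(scene, spec),
                                  sim.apply_fiber_bundle(scene, spec))
    with pytest.raises(ValueError):
        sim.BundleSpec(core_pitch=-1.0)
    with pytest.raises(ValueError):
        sim.BundleSpec(core_radius=0.0)


def test_bundle_transmission_cv_increases_core_variance():
    scene = np.full((96, 96), 0.8)
    centers = sim.hex_core_centers(96, 96, 8.0)
    ci = np.round(centers[:, 0]).astype(int)
    cj = np.round(centers[:, 1]).astype(int)
    keep = (ci > 4) & (ci < 92) & (cj > 4) & (cj < 92)

    def core_var(cv):
        spec = sim.BundleSpec(core_pitch=8.0, core_radius=1.2,
                              transmission_cv=cv, cladding_level=0.0, seed=11)
        out = sim.apply_fiber_bundle(scene, spec)
        return out[ci[keep], cj[keep]].var()

    assert core_var(0.3) > core_var(0.0)


def test_bundle_spectrum_has_ring_at_core_frequency():
    """The honeycomb pattern adds a spectral peak near 1/pitch absent
    from the input scene."""
    pitch = 6.0
    scene = sim.make_phantom(128, 128, "blobs", seed=2)
    out = sim.apply_fiber_bundle(scene, sim.BundleSpec(core_pitch=pitch, seed=4))

    def ring_power(img):
        f = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean()))) ** 2
        h, w = img.shape
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - h / 2, xx - w / 2)
        f_target = h / pitch          # radius (cycles per image) of the ring
        ring = (r > 0.85 * f_target) & (r < 1.25 * f_target)
        low = (r > 2) & (r < 0.5 * f_target)
        return f[ring].mean() / f[low].mean()

    assert ring_power(out) > 5 * ring_power(scene)


# ---------------------------------------------------------------------------
# noise models


def test_gaussian_zero_intensity_is_identity(cells_scene):
    out = sim.add_noise(cells_scene, sim.NoiseModelSpec("gaussian", 0.0, 1))
    np.testing.assert_array_equal(out, cells_scene)


def test_gaussian_intensity_matches_sample_std():
    clean = np.full((256, 256), 0.5)
    noisy = sim.add_noise(clean, sim.NoiseModelSpec("gaussian", 0.1, 2))
    assert abs((noisy - clean).std() - 0.1) < 0.01


def test_salt_pepper_corruption_fraction():
    clean = np.full((256, 256), 0.5)
    noisy = sim.add_noise(clean, sim.NoiseModelSpec("salt_pepper", 0.2, 3))
    frac = np.isin(noisy, (0.0, 1.0)).mean()
    assert abs(frac - 0.2) < 0.02
    # salt and pepper in roughly equal measure
    assert abs((noisy == 0).mean() - 0.1) < 0.02


def test_poisson_noise_scales_with_photon_count(cells_scene):
    lo = sim.add_noise(cells_scene, sim.NoiseModelSpec("poisson", 20.0, 4))
    hi = sim.add_noise(cells_scene, sim.NoiseModelSpec("poisson", 2000.0, 4))
    assert np.abs(lo - cells_scene).mean() > np.abs(hi - cells_scene).mean()


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        sim.NoiseModelSpec("speckle", 0.1)
    with pytest.raises(ValueError):
        sim.NoiseModelSpec("gaussian", -0.1)
    with pytest.raises(ValueError):
        sim.NoiseModelSpec("salt_pepper", 1.5)


# ---------------------------------------------------------------------------
# stacks


def test_stack_frames_differ_and_zero_noise_collapses(cells_scene):
    stack = sim.make_stack(cells_scene, sim.NoiseModelSpec("gaussian", 0.1, 5), 4)
    assert stack.n_frames == 4
    assert np.any(stack.frames[0] != stack.frames[1])
    flat = sim.make_stack(cells_scene, sim.NoiseModelSpec("gaussian", 0.0, 5), 3)
    for f in flat.frames:
        np.testing.assert_array_equal(f, cells_scene)
    with pytest.raises(ValueError):
        sim.make_stack(cells_scene, sim.NoiseModelSpec("gaussian", 0.1, 5), 1)


def test_average_stack_permutation_invariant(cells_scene, rng):
    stack = sim.make_stack(cells_scene, sim.NoiseModelSpec("gaussian", 0.1, 6), 8)
    avg = sim.average_stack(stack)
    perm = rng.permutation(8)
    avg2 = sim.average_stack(sim.FrameStack(stack.frames[perm], cells_scene))
    np.testing.assert_allclose(avg, avg2, atol=1e-12)


def test_frame_averaging_follows_sqrt_n_law(cells_scene):
    """RMSE(average, scene) ~ sigma/sqrt(N) within a factor of 2."""
    sigma = 0.1
    for n in (4, 16, 64):
        stack = sim.make_stack(cells_scene, sim.NoiseModelSpec("gaussian", sigma, 7), n)
        rmse = np.sqrt(np.mean((sim.average_stack(stack) - cells_scene) ** 2))
        expected = sigma / np.sqrt(n)
        assert expected / 2 < rmse < expected * 2, (n, rmse, expected)


def test_noise_map_recovers_homogeneous_level(cells_scene):
    stack = sim.make_stack(cells_scene, sim.NoiseModelSpec("gaussian", 0.05, 8), 200)
    nm = sim.noise_map_from_stack(stack)
    assert abs(nm.mean() - 0.05) / 0.05 < 0.15


def test_noise_map_normalization_and_degenerate_stack(cells_scene):
    stack = sim.make_stack(cells_scene, sim.NoiseModelSpec("gaussian", 0.05, 9), 16)
    nm = sim.noise_map_from_stack(stack, normalize=True)
    assert nm.max() == pytest.approx(1.0)
    ident = sim.FrameStack(np.stack([cells_scene] * 3), cells_scene)
    np.testing.assert_array_equal(sim.noise_map_from_stack(ident, normalize=True), 0.0)


def test_noise_map_tracks_spatial_ramp(cells_scene):
    """Column-ramped sigma (0.02 -> 0.12): stack map correlates r >= 0.95.

    The scene is rescaled into mid-range so border clipping does not
    distort the per-pixel noise statistics.
    """
    scene = 0.3 + 0.4 * cells_scene
    h, w = scene.shape
    ramp = np.linspace(0.02, 0.12, w)
    rng = np.random.default_rng(10)
    frames = np.clip(scene + rng.normal(0, 1, (200, h, w)) * ramp, 0, 1)
    nm = sim.noise_map_from_stack(sim.FrameStack(frames, scene))
    true_map = np.broadcast_to(ramp, (h, w))
    r = np.corrcoef(nm.ravel(), true_map.ravel())[0, 1]
    assert r >= 0.95
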