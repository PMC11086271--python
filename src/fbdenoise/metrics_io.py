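"""Full-reference metrics, image I/O and the Gaussian-blur reference filter.

PSNR is computed on the [0,1] intensity scale as ``10*log10(peak^2/MSE)``
and capped (default 100 dB) when the MSE vanishes, so reports stay
finite and serializable.  SSIM delegates to scikit-image with the
standard 7-pixel window and stabilizer constants for ``data_range=1``.

I/O covers 8/16-bit PNG and 8/16-bit integer or 32-bit float TIFF,
single images and multi-page stacks; RGB inputs are collapsed to
luminance (Rec. 601 weights) as a convenience -- the target modalities
are single-channel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = [
    "MetricReport",
    "psnr",
    "ssim",
    "gaussian_reference",
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "write_report",
]

PSNR_CAP_DB = 100.0


@dataclass
class MetricReport:
    image_id: str
    psnr: float
    ssim: float


def psnr(a, b, peak=1.0, cap=PSNR_CAP_DB):
    """Peak signal-to-noise ratio in dB between two same-shape images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("psnr: shape mismatch")
    mse = np.mean((a - b) ** 2)
    if mse == 0.0:
        return float(cap)
    return float(min(cap, 10.0 * np.log10(peak * peak / mse)))


def ssim(a, b, window=7):
    """Mean structural similarity on the [0,1] range."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("ssim: shape mismatch")
    if min(a.shape) < window:
        raise ValueError("image smaller than the SSIM window")
    return float(structural_similarity(a, b, win_size=window, data_range=1.0))


def gaussian_reference(noisy, sigma=1.0):
    """Classical Gaussian low-pass baseline with reflect boundaries."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    noisy = np.asarray(noisy, dtype=np.float64)
    return ndimage.gaussian_filter(noisy, sigma, mode="reflect")


# ---------------------------------------------------------------------------
# image I/O


_REC601 = np.array([0.299, 0.587, 0.114])


def _to_float01(arr):
    float_src = np.issubdtype(arr.dtype, np.floating)
    if not float_src:
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and not float_src:
            arr = arr[..., :3] @ _REC601
        elif arr.shape[-1] in (3, 4):
            raise ValueError("multi-channel float images are not supported")
        else:
            raise ValueError("unsupported channel layout")
    return np.asarray(arr, dtype=np.float64)


def read_image(path):
    """Read a PNG/TIFF image as a float grid; integer data scaled to [0,1]."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    return _to_float01(np.asarray(arr))


def write_image(image, path, dtype="float32"):
    """Write a single image; ``dtype`` in {uint8, uint16, float32}.

    PNG supports uint8/uint16; TIFF additionally float32 (lossless for
    [0,1] float data).
    """
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    suffix = path.suffix.lower()
    if dtype == "float32":
        if suffix not in (".tif", ".tiff"):
            raise ValueError("float32 output requires TIFF")
        tifffile.imwrite(path, image.astype(np.float32))
        return
    info = np.iinfo(np.dtype(dtype))
    quant = np.round(np.clip(image, 0, 1) * info.max).astype(dtype)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, quant)
    elif suffix == ".png":
        iio.imwrite(path, quant)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")


def read_stack(path):
    """Read a multi-page TIFF as an (N, H, W) float array."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    return np.stack([_to_float01(frame) for frame in arr])


def write_stack(frames, path, dtype="float32"):
    """Write an (N, H, W) array as a multi-page TIFF."""
    frames = np.asarray(frames, dtype=np.float64)
    if dtype == "float32":
        out = frames.astype(np.float32)
    else:
        info = np.iinfo(np.dtype(dtype))
        out = np.round(np.clip(frames, 0, 1) * info.max).astype(dtype)
    tifffile.imwrite(path, out, photometric="minisblack")


def write_report(reports, path):
    """Write metric rows as CSV with header ``image_id,psnr_db,ssim``."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image_id", "psnr_db", "ssim"])
        for r in reports:
            wr.writerow([r.image_id, f"{r.psnr:.4f}", f"{r.ssim:.6f}"])
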