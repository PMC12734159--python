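"""Image preprocessing chain and training-time augmentation.

The fixed evaluation-time chain standardises every input image:

1. resize to a square side (default 224), bilinear;
2. RGB -> grayscale with luminance weights (0.299, 0.587, 0.114);
3. unsharp mask: ``img + amount * (img - blur(img))`` with a Gaussian blur
   of sigma = radius / 3 (a named radius truncated at three sigma);
4. Sobel edge enhancement: ``img + weight * |grad|`` with the standard 3x3
   Sobel kernels.

Every step clips back into [0, 1] where it can leave the range, and the
whole chain is deterministic.  Augmentation (random rotation within +-15
degrees, horizontal flip, translation up to 10% of the side, brightness and
contrast within +-10%) is applied only during training, each transform
independently with probability 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "load_image",
    "resize_to_standard",
    "to_grayscale",
    "unsharp_mask",
    "sobel_magnitude",
    "sobel_enhance",
    "preprocess_chain",
    "AugmentConfig",
    "augment",
    "rotate_image",
]

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])
SOBEL_GX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_GY = SOBEL_GX.T


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG/TIFF into a float array in [0, 1] (H x W or H x W x 3)."""
    with PILImage.open(path) as handle:
        img = handle.convert("RGB") if handle.mode not in ("L", "RGB") else handle
        arr = np.asarray(img, dtype=np.float64) / 255.0
    return arr


def resize_to_standard(img: np.ndarray, side: int = 224) -> np.ndarray:
    """Bilinear resize to ``side x side`` (anti-aliased when downscaling)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3) or min(img.shape[:2]) < 2:
        raise ValueError("expected an image with at least 2 pixels per axis")
    if img.shape[:2] == (side, side):
        return img.copy()
    shape = (side, side) + img.shape[2:]
    down = side < max(img.shape[:2])
    out = _sk_resize(img, shape, order=1, anti_aliasing=down, preserve_range=True,
                     mode="reflect")
    return np.clip(out, 0.0, 1.0)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse RGB to a single luminance channel; identity if already 2-D."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img.copy()
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0].copy()
    if img.ndim == 3 and img.shape[2] == 3:
        return img @ GRAY_WEIGHTS
    raise ValueError(f"expected 1 or 3 channels, got shape {img.shape}")


def unsharp_mask(img: np.ndarray, radius: float = 100.0, amount: float = 1.0
                 ) -> np.ndarray:
    """Sharpen by adding back the high-pass residual of a Gaussian blur."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    img = np.asarray(img, dtype=np.float64)
    blurred = ndimage.gaussian_filter(img, sigma=radius / 3.0, truncate=3.0,
                                      mode="reflect")
    return np.clip(img + amount * (img - blurred), 0.0, 1.0)


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Unnormalised gradient magnitude sqrt(Gx^2 + Gy^2), 3x3 Sobel kernels."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("Sobel enhancement expects a grayscale image")
    gx = ndimage.convolve(img, SOBEL_GX, mode="reflect")
    gy = ndimage.convolve(img, SOBEL_GY, mode="reflect")
    return np.sqrt(gx**2 + gy**2)


def sobel_enhance(img: np.ndarray, weight: float = 0.5) -> np.ndarray:
    """Additively highlight edges: ``clip(img + weight * |grad|, 0, 1)``."""
    return np.clip(img + weight * sobel_magnitude(img), 0.0, 1.0)


def preprocess_chain(
    img: np.ndarray,
    side: int = 224,
    unsharp_radius: float = 100.0,
    unsharp_amount: float = 1.0,
    sobel_weight: float = 0.5,
) -> np.ndarray:
    """resize -> grayscale -> unsharp mask -> Sobel enhancement."""
    out = resize_to_standard(img, side)
    out = to_grayscale(out)
    out = unsharp_mask(out, unsharp_radius, unsharp_amount)
    return sobel_enhance(out, sobel_weight)


def rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear rotation about the centre, edge-padded, shape preserved."""
    return _sk_rotate(img, angle_deg, order=1, mode="edge", preserve_range=True)


@dataclass(frozen=True)
class AugmentConfig:
    """Bounds of the random training-time transforms."""

    rotation_deg: float = 15.0
    translate_frac: float = 0.10
    brightness: float = 0.10
    contrast: float = 0.10
    probability: float = 0.5  # per-transform application probability


def augment(img: np.ndarray, rng, cfg: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Randomly perturb a standardised grayscale image (training only).

    Each transform — rotation, horizontal flip, translation, brightness /
    contrast — fires independently with ``cfg.probability``, its parameter
    drawn uniformly within the configured bounds.  ``rng`` needs ``random()``
    and ``uniform(lo, hi)``; the output shape equals the input shape.
    """
    out = np.asarray(img, dtype=np.float64)
    if rng.random() < cfg.probability:
        out = rotate_image(out, rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    if rng.random() < cfg.probability:
        out = out[:, ::-1].copy()
    if rng.random() < cfg.probability:
        side = max(out.shape)
        dy = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * side
        dx = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * side
        out = ndimage.shift(out, (dy, dx), order=1, mode="nearest")
    if rng.random() < cfg.probability:
        gain = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        offset = rng.uniform(-cfg.brightness, cfg.brightness)
        out = (out - 0.5) * gain + 0.5 + offset
    return np.clip(out, 0.0, 1.0)
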