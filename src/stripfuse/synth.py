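"""Synthetic four-class brain phantom generator.

Real multi-source MRI datasets are large and cannot ship with a package, so
the whole pipeline is exercised on seeded phantoms instead: an elliptical
"brain" on a dark background with smooth internal texture, optional additive
Gaussian noise, and a class-dependent bright lesion.

Classes (folder names mirror the usual glioma/meningioma/pituitary/notumor
dataset layout so the real-data loader and the synthetic loader share one
code path):

* ``elongated`` (glioma)   — a curved, jagged high-intensity strip, strongly
  anisotropic; this is the shape strip pooling is designed for.
* ``compact`` (meningioma) — a round blob near the brain boundary.
* ``central`` (pituitary)  — a small bright blob near the brain centroid.
* ``none`` (notumor)       — texture only, no lesion.

Lesions are parametric (Bezier strip / disc / small disc) with per-seed
jitter, and the generator retains its own ground-truth lesion mask so tests
can compare the rendered image against an exact oracle.  Everything is
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from scipy.ndimage import gaussian_filter

from .data import DatasetManifest, ManifestRecord

__all__ = [
    "PhantomSpec",
    "PhantomClassError",
    "CLASS_LABELS",
    "CLASS_FOLDERS",
    "render_phantom",
    "generate_phantom",
    "generate_dataset",
]

CLASS_LABELS = ("elongated", "compact", "central", "none")
#: phantom class -> dataset folder name (Kaggle-style layout)
CLASS_FOLDERS = {
    "elongated": "glioma",
    "compact": "meningioma",
    "central": "pituitary",
    "none": "notumor",
}


class PhantomClassError(ValueError):
    """Raised for a class label outside the four phantom classes."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom image.

    ``lesion_intensity`` is the peak lesion brightness in [0, 1]; brain
    texture always stays below it.  ``noise_sigma`` is the standard
    deviation of the additive Gaussian noise (0 disables noise).
    """

    class_label: str
    image_side: int = 224
    lesion_intensity: float = 0.85
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise PhantomClassError(
                f"unknown class {self.class_label!r}; expected one of {CLASS_LABELS}"
            )
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.lesion_intensity <= 1.0:
            raise ValueError("lesion_intensity must lie in [0, 1]")


def _stamp_discs(mask: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> None:
    """Fill discs (vectorised per disc over a local bounding box) into ``mask``."""
    side = mask.shape[0]
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = max(0, int(cy - r) - 1), min(side, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(side, int(cx + r) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator,
                 center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Binary lesion support for the spec's class; empty for class ``none``."""
    s = spec.image_side
    mask = np.zeros((s, s), dtype=bool)
    label = spec.class_label
    if label == "none":
        return mask

    if label == "elongated":
        # quadratic Bezier strip, axis-aligned +- jitter, jagged thickness
        vertical = rng.random() < 0.5
        half_len = rng.uniform(0.23, 0.28) * s
        if vertical:
            half_len *= 0.85  # shorter axis of the brain ellipse
        sag = rng.uniform(0.015, 0.035) * s * rng.choice((-1.0, 1.0))
        tau = rng.uniform(0.018, 0.028) * s  # base half-thickness
        mid = center + rng.uniform(-0.03, 0.03, size=2) * s
        t = np.linspace(0.0, 1.0, 256)
        along = (2.0 * t - 1.0) * half_len
        across = sag * 4.0 * t * (1.0 - t)  # Bezier bulge
        if vertical:
            pts = np.stack([mid[0] + along, mid[1] + across], axis=1)
        else:
            pts = np.stack([mid[0] + across, mid[1] + along], axis=1)
        # jagged boundary: smooth random modulation of the thickness
        wobble = gaussian_filter(rng.standard_normal(t.size), sigma=6.0, mode="wrap")
        wobble = wobble / (np.abs(wobble).max() + 1e-9)
        radii = tau * (1.0 + 0.3 * wobble)
        _stamp_discs(mask, pts, radii)
        return mask

    if label == "compact":
        radius = rng.uniform(0.055, 0.085) * s
        angle = rng.uniform(0.0, 2.0 * np.pi)
        cy = center[0] + 0.62 * axes[0] * np.sin(angle)
        cx = center[1] + 0.62 * axes[1] * np.cos(angle)
        _stamp_discs(mask, np.array([[cy, cx]]), np.array([radius]))
        return mask

    # central: small blob near the centroid
    radius = rng.uniform(0.030, 0.045) * s
    off = rng.uniform(-0.04, 0.04, size=2) * s
    _stamp_discs(mask, np.array([center + off]), np.array([radius]))
    return mask


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom; returns ``(image, lesion_mask)``.

    The image is a float array in [0, 1]; the mask is the ground-truth
    boolean lesion support before noise was added.
    """
    s = spec.image_side
    class_index = CLASS_LABELS.index(spec.class_label)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), class_index]))

    center = (0.5 + rng.uniform(-0.015, 0.015, size=2)) * s
    axes = np.array(
        [0.40 * rng.uniform(0.92, 1.0), 0.34 * rng.uniform(0.92, 1.0)]
    ) * s  # (vertical, horizontal) semi-axes
    yy, xx = np.mgrid[0:s, 0:s]
    ellipse = ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2
    brain = np.clip((1.0 - ellipse) * 8.0, 0.0, 1.0)  # soft-edged support

    texture = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 16.0)
    texture = texture / (np.abs(texture).max() + 1e-9)
    interior = np.clip(0.32 + 0.12 * texture, 0.0, 0.60)
    img = 0.02 + brain * (interior - 0.02)

    mask = _lesion_mask(spec, rng, center, axes)
    if mask.any():
        soft = np.clip(gaussian_filter(mask.astype(float), sigma=0.01 * s) * 1.4, 0.0, 1.0)
        img = np.maximum(img, spec.lesion_intensity * soft)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(s, s))
    return np.clip(img, 0.0, 1.0), mask


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """The phantom image alone (see :func:`render_phantom`)."""
    return render_phantom(spec)[0]


def _image_seed(seed: int, class_index: int, index: int) -> int:
    return (int(seed) * 1_000_003 + class_index * 10_007 + index) % (2**31)


def generate_dataset(
    n_per_class: int,
    out_dir: str | Path,
    seed: int,
    image_side: int = 224,
    lesion_intensity: float = 0.85,
    noise_sigma: float = 0.02,
) -> DatasetManifest:
    """Write ``4 * n_per_class`` phantom PNGs in a class-folder layout.

    Layout is ``<out_dir>/<folder>/<global_id>.png`` with the four folders of
    :data:`CLASS_FOLDERS`.  Returns a manifest with unique global IDs (split
    column unassigned).  Fully reproducible: the same seed yields identical
    manifests and identical file bytes.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    records = []
    for class_index, label in enumerate(CLASS_LABELS):
        folder = out_dir / CLASS_FOLDERS[label]
        folder.mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            img_seed = _image_seed(seed, class_index, i)
            spec = PhantomSpec(
                class_label=label,
                image_side=image_side,
                lesion_intensity=lesion_intensity,
                noise_sigma=noise_sigma,
                seed=img_seed,
            )
            img = generate_phantom(spec)
            global_id = f"syn{seed:04d}-{CLASS_FOLDERS[label]}-{i:05d}"
            path = folder / f"{global_id}.png"
            PILImage.fromarray(np.round(img * 255.0).astype(np.uint8)).save(path)
            records.append(
                ManifestRecord(
                    global_id=global_id,
                    source_id=f"{CLASS_FOLDERS[label]}_{i:05d}",
                    path=str(path),
                    class_label=label,
                    split="unassigned",
                )
            )
    return DatasetManifest(records)
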