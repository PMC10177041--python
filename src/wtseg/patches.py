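"""Training-patch sampling at the working resolution, plus augmentation.

Patches are sampled from the annotated regions of a labeled image after
resampling it from its base pixel spacing (0.24 μm/pixel for the
emulated scanners) to the working spacing of 0.5 μm/pixel — bilinear
for pixels, nearest for labels.  The patch center is always an
annotated pixel; in class-balanced mode a class present in the image is
drawn uniformly first and then a pixel of that class, which counters
the severe class imbalance of sparse annotations.  Borders are
mirror-padded.

Augmentation applies right-angle rotations and flips identically to
pixels and labels, and Gaussian blur, Gaussian noise and HSV color
jitter to pixels only, each gated by its own probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

from .annotations import LabeledImage
from .taxonomy import UNANNOTATED

__all__ = [
    "PatchSpec",
    "AugmentationConfig",
    "resample_image",
    "sample_patch",
    "augment",
]


@dataclass
class PatchSpec:
    shape: tuple[int, int] = (412, 412)
    spacing: float = 0.5  # μm/pixel working resolution
    class_balanced: bool = True

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError("patch shape must be positive")
        if self.spacing <= 0:
            raise ValueError("sampling spacing must be positive")


@dataclass
class AugmentationConfig:
    rotation_set: tuple[int, ...] = (0, 90, 180, 270)
    p_rotate: float = 1.0
    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    p_blur: float = 0.25
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    p_noise: float = 0.25
    noise_sd: tuple[float, float] = (0.01, 0.05)  # on [0,1] pixels
    p_color: float = 0.5
    hue_amp: float = 0.02
    saturation_amp: float = 0.1
    value_amp: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.p_rotate, self.p_flip_h, self.p_flip_v, self.p_blur,
                  self.p_noise, self.p_color):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(a % 90 for a in self.rotation_set):
            raise ValueError("rotations are restricted to right angles")
        if min(self.hue_amp, self.saturation_amp, self.value_amp) < 0:
            raise ValueError("color amplitudes must be non-negative")


def resample_image(image: LabeledImage, spacing: float) -> LabeledImage:
    """Rescale an image to a target spacing (bilinear pixels, nearest labels)."""
    if spacing == image.spacing:
        return image
    scale = image.spacing / spacing
    h, w = image.labels.shape
    out_shape = (max(1, round(h * scale)), max(1, round(w * scale)))
    pixels = resize(
        image.pixels, out_shape, order=1, preserve_range=True,
        anti_aliasing=False,
    ).astype(np.uint8)
    labels = resize(
        image.labels, out_shape, order=0, preserve_range=True,
        anti_aliasing=False,
    ).astype(image.labels.dtype)
    dense = None
    if image.dense_labels is not None:
        dense = resize(
            image.dense_labels, out_shape, order=0, preserve_range=True,
            anti_aliasing=False,
        ).astype(image.dense_labels.dtype)
    return LabeledImage(pixels, labels, spacing, image.case_id, dense)


def _crop_mirror(arr: np.ndarray, r: int, c: int, h: int, w: int) -> np.ndarray:
    """Crop [r0,r0+h)x[c0,c0+w) centered at (r,c) with mirror padding."""
    r0, c0 = r - h // 2, c - w // 2
    hh, ww = arr.shape[:2]
    pr0, pc0 = max(0, -r0), max(0, -c0)
    pr1, pc1 = max(0, r0 + h - hh), max(0, c0 + w - ww)
    sub = arr[max(0, r0): r0 + h, max(0, c0): c0 + w]
    if pr0 or pc0 or pr1 or pc1:
        pad = [(pr0, pr1), (pc0, pc1)] + [(0, 0)] * (arr.ndim - 2)
        sub = np.pad(sub, pad, mode="symmetric")
    return sub


def sample_patch(
    image: LabeledImage,
    spec: PatchSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one patch: (float32 pixels in [0,1], uint8 labels).

    The image is brought to the working spacing first (no-op when it is
    there already, so callers may pre-resample once).  The center pixel
    is guaranteed annotated.
    """
    image = resample_image(image, spec.spacing)
    coords = np.argwhere(image.labels != UNANNOTATED)
    if coords.size == 0:
        raise ValueError(f"case {image.case_id!r} has no annotated pixels")
    if spec.class_balanced:
        present = np.unique(image.labels[image.labels != UNANNOTATED])
        cls = present[rng.integers(len(present))]
        coords = np.argwhere(image.labels == cls)
    r, c = coords[rng.integers(len(coords))]
    h, w = spec.shape
    pixels = _crop_mirror(image.pixels, r, c, h, w).astype(np.float32) / 255.0
    labels = _crop_mirror(image.labels, r, c, h, w)
    return pixels, labels


def augment(
    pixels: np.ndarray,
    labels: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the augmentation stack to one patch.

    Geometric transforms act on pixels and labels together; photometric
    transforms never touch the labels.
    """
    pixels = np.asarray(pixels, dtype=np.float32)
    if rng.random() < config.p_rotate:
        angle = config.rotation_set[rng.integers(len(config.rotation_set))]
        k = (angle // 90) % 4
        if k:
            pixels = np.rot90(pixels, k, axes=(0, 1))
            labels = np.rot90(labels, k, axes=(0, 1))
    if rng.random() < config.p_flip_h:
        pixels = pixels[:, ::-1]
        labels = labels[:, ::-1]
    if rng.random() < config.p_flip_v:
        pixels = pixels[::-1]
        labels = labels[::-1]
    if rng.random() < config.p_blur:
        sigma = rng.uniform(*config.blur_sigma)
        pixels = ndimage.gaussian_filter(pixels, sigma=(sigma, sigma, 0))
    if rng.random() < config.p_noise:
        sd = rng.uniform(*config.noise_sd)
        pixels = pixels + rng.standard_normal(pixels.shape).astype(np.float32) * sd
    if rng.random() < config.p_color:
        hsv = rgb2hsv(np.clip(pixels, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-config.hue_amp, config.hue_amp)) % 1.0
        hsv[..., 1] += rng.uniform(-config.saturation_amp, config.saturation_amp)
        hsv[..., 2] += rng.uniform(-config.value_amp, config.value_amp)
        pixels = hsv2rgb(np.clip(hsv, 0.0, 1.0)).astype(np.float32)
    return np.clip(pixels, 0.0, 1.0).astype(np.float32), np.ascontiguousarray(labels)
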