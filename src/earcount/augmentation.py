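"""Training-time augmentation: random crop, random flips, random hue shift.

All randomness flows through an explicit ``numpy.random.Generator``, so a
fixed seed reproduces augmented batches bit-for-bit.  Images are float32
RGB arrays of shape (H, W, 3) with values in [0, 1]; point annotations are
transformed jointly with the pixels so density supervision stays aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

from .annotation_io import PointAnnotationSet


@dataclass(frozen=True)
class AugmentationConfig:
    crop_size: int = 512
    flip_probability: float = 0.5
    hue_probability: float = 0.5
    hue_max_shift: float = 0.1  # fraction of the hue circle
    seed: int | None = None

    def __post_init__(self):
        for name in ("flip_probability", "hue_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.crop_size < 1:
            raise ValueError("crop_size must be positive")


def random_crop(image: np.ndarray, points: PointAnnotationSet, size: int,
                rng: np.random.Generator):
    """Uniformly sample a size x size window; keep points whose centre falls
    inside it, shifted to window coordinates."""
    h, w = image.shape[:2]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image {w}x{h}")
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    crop = image[top:top + size, left:left + size]
    pts = points.points
    if len(pts):
        keep = ((pts[:, 0] >= left) & (pts[:, 0] < left + size) &
                (pts[:, 1] >= top) & (pts[:, 1] < top + size))
        pts = pts[keep] - np.array([left, top], dtype=np.float64)
    out = PointAnnotationSet(image_id=points.image_id, image_size=(size, size),
                             points=pts)
    return crop, out


def flip_horizontal(image: np.ndarray, points: PointAnnotationSet):
    """Mirror the image left-right and map points x -> width - 1 - x."""
    w = points.image_size[0]
    pts = points.points.copy()
    if len(pts):
        pts[:, 0] = (w - 1) - pts[:, 0]
        pts[:, 0] = np.clip(pts[:, 0], 0.0, np.nextafter(float(w), 0.0))
    return image[:, ::-1].copy(), PointAnnotationSet(
        image_id=points.image_id, image_size=points.image_size, points=pts)


def flip_vertical(image: np.ndarray, points: PointAnnotationSet):
    h = points.image_size[1]
    pts = points.points.copy()
    if len(pts):
        pts[:, 1] = (h - 1) - pts[:, 1]
        pts[:, 1] = np.clip(pts[:, 1], 0.0, np.nextafter(float(h), 0.0))
    return image[::-1, :].copy(), PointAnnotationSet(
        image_id=points.image_id, image_size=points.image_size, points=pts)


def random_flip(image: np.ndarray, points: PointAnnotationSet, p: float,
                rng: np.random.Generator, axes: str = "hv"):
    """Independently flip along each enabled axis with probability ``p``;
    the image and the point set share each flip decision."""
    if "h" in axes and rng.random() < p:
        image, points = flip_horizontal(image, points)
    if "v" in axes and rng.random() < p:
        image, points = flip_vertical(image, points)
    return image, points


def shift_hue(image: np.ndarray, shift: float) -> np.ndarray:
    """Rotate the hue channel by ``shift`` (fraction of the hue circle)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    hsv = rgb2hsv(image.astype(np.float64))
    hsv[..., 0] = np.mod(hsv[..., 0] + shift, 1.0)
    return hsv2rgb(hsv).astype(np.float32)


def random_hue(image: np.ndarray, p: float, max_shift: float,
               rng: np.random.Generator) -> np.ndarray:
    """With probability ``p``, shift hue by a uniform draw in
    [-max_shift, +max_shift]; geometry (and any point set) is untouched."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    if rng.random() < p:
        return shift_hue(image, float(rng.uniform(-max_shift, max_shift)))
    return image


def augment(image: np.ndarray, points: PointAnnotationSet,
            config: AugmentationConfig, rng: np.random.Generator):
    """Full training-time pipeline: crop, then hue, then flips."""
    image, points = random_crop(image, points, config.crop_size, rng)
    image = random_hue(image, config.hue_probability, config.hue_max_shift, rng)
    image, points = random_flip(image, points, config.flip_probability, rng)
    return image, points
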