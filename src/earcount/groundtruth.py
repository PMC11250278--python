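"""Ground-truth density and attention maps from point annotations.

A wheat-ear image annotated with N centre points is represented as an
impulse grid H (one unit of mass per ear) smoothed with a fixed-bandwidth
Gaussian kernel into a density map F whose integral equals N exactly: the
kernel stamped for each point is renormalised by its in-grid mass, so ears
near the border still contribute one full count.

The binary attention ground truth marks ear-bearing regions: the density map
is smoothed once more with the same Gaussian (zero-padded, same-size output)
and thresholded at ``th`` (active where the smoothed value is >= th).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .annotation_io import PointAnnotationSet

DEFAULT_SIGMA = 8.0       # px, at the 1024-px image scale
DEFAULT_THRESHOLD = 1e-3  # attention threshold on the re-smoothed density


@dataclass(frozen=True)
class GaussianKernel:
    """A unit-sum, centred, radially symmetric discrete Gaussian."""

    sigma: float
    radius: int
    weights: np.ndarray  # (2r+1, 2r+1)

    @property
    def weights_1d(self) -> np.ndarray:
        """Normalised 1-D factor (the 2-D kernel is its outer product)."""
        r = self.radius
        w = np.exp(-np.arange(-r, r + 1, dtype=np.float64) ** 2 / (2 * self.sigma ** 2))
        return w / w.sum()


def gaussian_kernel(sigma: float, radius: int) -> GaussianKernel:
    """Build the discrete Gaussian window used for density smoothing."""
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(radius)
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma ** 2))
    w /= w.sum()
    return GaussianKernel(sigma=float(sigma), radius=radius, weights=w)


def default_radius(sigma: float) -> int:
    """Kernel radius ceil(3*sigma): truncates <0.3% of the Gaussian mass."""
    return max(1, int(np.ceil(3.0 * sigma)))


def _rounded_indices(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Round half-up to pixel indices; points must be in [0,W) x [0,H)."""
    h, w = shape
    xs, ys = points[:, 0], points[:, 1]
    bad = (xs < 0) | (xs >= w) | (ys < 0) | (ys >= h) | ~np.isfinite(xs) | ~np.isfinite(ys)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"point {tuple(points[i])} lies outside the {w}x{h} image domain")
    cols = np.minimum(np.floor(xs + 0.5).astype(int), w - 1)
    rows = np.minimum(np.floor(ys + 0.5).astype(int), h - 1)
    return np.stack([rows, cols], axis=1)


def make_density_map(annotations: PointAnnotationSet | np.ndarray,
                     shape: tuple[int, int],
                     sigma: float = DEFAULT_SIGMA,
                     radius: int | None = None) -> np.ndarray:
    """Density map F of ``shape`` (H, W); its sum equals the point count.

    Each point stamps a unit-mass Gaussian at its rounded pixel; the stamped
    window is clipped to the grid and renormalised by its in-grid mass, so
    border points still contribute exactly one count.
    """
    points = (annotations.points if isinstance(annotations, PointAnnotationSet)
              else np.asarray(annotations, dtype=np.float64).reshape(-1, 2))
    h, w = int(shape[0]), int(shape[1])
    density = np.zeros((h, w), dtype=np.float64)
    if len(points) == 0:
        return density
    kernel = gaussian_kernel(sigma, radius if radius is not None else default_radius(sigma))
    r = kernel.radius
    for row, col in _rounded_indices(points, (h, w)):
        r0, r1 = max(row - r, 0), min(row + r + 1, h)
        c0, c1 = max(col - r, 0), min(col + r + 1, w)
        patch = kernel.weights[r0 - row + r:r1 - row + r, c0 - col + r:c1 - col + r]
        density[r0:r1, c0:c1] += patch / patch.sum()
    return density


def smooth_density(density: np.ndarray, sigma: float = DEFAULT_SIGMA,
                   radius: int | None = None) -> np.ndarray:
    """Z = density (*) Gaussian, same-size output with zero padding.

    The normalised 2-D Gaussian is separable, so the convolution is done as
    two 1-D passes.
    """
    kernel = gaussian_kernel(sigma, radius if radius is not None else default_radius(sigma))
    w1 = kernel.weights_1d
    z = correlate1d(np.asarray(density, dtype=np.float64), w1, axis=0, mode="constant")
    return correlate1d(z, w1, axis=1, mode="constant")


def make_attention_map(density: np.ndarray, sigma: float = DEFAULT_SIGMA,
                       th: float = DEFAULT_THRESHOLD,
                       radius: int | None = None) -> np.ndarray:
    """Binary attention ground truth: 1 where the re-smoothed density >= th."""
    if not th > 0:
        raise ValueError(f"threshold must be positive, got {th}")
    z = smooth_density(density, sigma=sigma, radius=radius)
    return (z >= th).astype(np.float64)


def count_from_density(density: np.ndarray) -> float:
    """The count encoded by a density map is its integral (plain sum)."""
    return float(np.asarray(density).sum())


def pool_to_stride(density: np.ndarray, stride: int) -> np.ndarray:
    """Mass-conserving downsample of a ground-truth map to a coarser grid.

    Values within each stride x stride cell are *summed*, so the integral
    (the count) is preserved; used when the network head emits a grid
    smaller than the input image.
    """
    if stride == 1:
        return np.asarray(density, dtype=np.float64)
    h, w = density.shape
    if h % stride or w % stride:
        raise ValueError(f"map shape {density.shape} not divisible by stride {stride}")
    return (np.asarray(density, dtype=np.float64)
            .reshape(h // stride, stride, w // stride, stride).sum(axis=(1, 3)))
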