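"""Seeded generator of wheat-field-like images with exact point ground truth.

The generator emulates the statistical difficulties of field imagery —
dense, small, elongated, mutually overlapping bright objects over a
cluttered darker background with an illumination gradient and sensor noise
— without attempting photorealism.  Each "ear" is an oriented ellipse with
mild internal texture; its exact centre is the ground-truth point.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from .annotation_io import PointAnnotationSet, write_points


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field image."""

    image_size: tuple[int, int] = (256, 256)       # (width, height)
    count_range: tuple[int, int] = (20, 120)       # ears per image, inclusive
    ear_major_axis: tuple[float, float] = (6.0, 12.0)   # px, half-axis range
    ear_minor_axis: tuple[float, float] = (2.0, 4.5)
    ear_intensity: tuple[float, float] = (0.55, 0.95)
    background_level: float = 0.22
    background_texture: float = 0.06     # amplitude of low-frequency clutter
    illumination_amplitude: float = 0.15  # linear gradient amplitude
    noise_sigma: float = 0.02            # additive Gaussian pixel noise
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.count_range
        if not (0 <= lo <= hi <= 10_000):
            raise ValueError(f"count_range must satisfy 0 <= lo <= hi <= 1e4")
        if min(self.ear_major_axis + self.ear_minor_axis) <= 0:
            raise ValueError("ear axes must be positive")


#: named presets; "wedd_like" mirrors a high-density 82-245 ears/image split
PRESETS: dict[str, FieldSpec] = {
    "desk": FieldSpec(),
    "wedd_like": FieldSpec(image_size=(512, 512), count_range=(82, 245)),
    "tiny": FieldSpec(image_size=(64, 64), count_range=(5, 20),
                      ear_major_axis=(3.0, 5.0), ear_minor_axis=(1.0, 2.0)),
}


def _background(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.image_size
    base = np.full((h, w), spec.background_level, dtype=np.float64)
    clutter = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 32.0)
    peak = np.abs(clutter).max()
    if peak > 0:
        base += spec.background_texture * clutter / peak
    # linear illumination gradient in a random direction
    theta = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (np.cos(theta) * xx / max(w - 1, 1) + np.sin(theta) * yy / max(h - 1, 1))
    base += spec.illumination_amplitude * (ramp - ramp.mean())
    return base


def generate_field(spec: FieldSpec,
                   rng: np.random.Generator | None = None,
                   image_id: str = "synthetic"):
    """Draw one field image; returns ``(image, PointAnnotationSet)``.

    The image is float32 RGB in [0, 1]; the point set holds the exact
    ellipse centres.  The same spec and seed reproduce identical bytes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    count = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))

    luma = _background(spec, rng)
    occupied = np.zeros((h, w), dtype=bool)
    centres = []
    margin = 1.0
    attempts_per_ear = 50
    for _ in range(count):
        placed = False
        for _ in range(attempts_per_ear):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            major = rng.uniform(*spec.ear_major_axis)
            minor = rng.uniform(*spec.ear_minor_axis)
            angle = rng.uniform(0.0, np.pi)
            rr, cc = ellipse(cy, cx, major, minor, shape=(h, w), rotation=angle)
            if rr.size == 0:
                continue
            if not spec.allow_overlap and occupied[rr, cc].any():
                continue
            intensity = rng.uniform(*spec.ear_intensity)
            # mild per-ear texture: awn-like brightness modulation
            tex = 1.0 + 0.2 * np.sin(0.9 * rr + 1.3 * cc + rng.uniform(0, 2 * np.pi))
            luma[rr, cc] = np.maximum(luma[rr, cc], intensity * tex * 0.5 + intensity * 0.5)
            occupied[rr, cc] = True
            centres.append((cx, cy))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {count} non-overlapping ears in {w}x{h}")

    luma += spec.noise_sigma * rng.standard_normal((h, w))
    luma = np.clip(luma, 0.0, 1.0)
    # wheat-ish colouring: ears skew yellow, background skews green-brown
    image = np.stack([luma * 0.95, luma * 0.85 + 0.03, luma * 0.45], axis=-1)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    points = PointAnnotationSet(image_id=image_id, image_size=(w, h),
                                points=np.array(centres, dtype=np.float64).reshape(-1, 2))
    return image, points


def generate_split(spec: FieldSpec, n_images: int, out_dir,
                   seed: int | None = None, prefix: str = "field"):
    """Write ``n_images`` PNGs plus a points CSV and a JSON manifest.

    Returns the list of generated :class:`PointAnnotationSet`.  The manifest
    records the spec and seed, so the dataset can be regenerated
    byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    annotations = []
    for i, child in enumerate(child_seeds):
        image_id = f"{prefix}_{i:04d}.png"
        img, pts = generate_field(spec, np.random.default_rng(int(child)), image_id)
        iio.imwrite(out_dir / image_id, (img * 255.0 + 0.5).astype(np.uint8))
        annotations.append(pts)
    write_points(annotations, out_dir / "points.csv")
    manifest = {"spec": asdict(spec), "seed": seed, "n_images": int(n_images),
                "prefix": prefix,
                "image_ids": [a.image_id for a in annotations]}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return annotations


def regenerate_from_manifest(manifest_path, out_dir):
    """Re-create a split from its manifest (byte-identical)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    spec_dict = dict(manifest["spec"])
    for key in ("image_size", "count_range", "ear_major_axis",
                "ear_minor_axis", "ear_intensity"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = FieldSpec(**spec_dict)
    return generate_split(spec, manifest["n_images"], out_dir,
                          seed=manifest["seed"], prefix=manifest["prefix"])


def dataset_hash(directory) -> str:
    """SHA-256 over all files of a generated split (order-stable)."""
    digest = hashlib.sha256()
    for path in sorted(Path(directory).iterdir()):
        if path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
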