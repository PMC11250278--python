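"""Configuration, training loop, checkpointing and prediction.

The trainer consumes a directory produced by :mod:`earcount.synthetic`
(or any directory of PNG/JPEG images plus an ``image_id,x,y`` points CSV),
draws augmented crops, supervises the two network heads with the combined
density / local-consistency / attention objective, and logs per-step loss
components to CSV.  Everything is seeded: configuration + seed fully
determine the log on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .annotation_io import PointAnnotationSet, read_points
from .augmentation import AugmentationConfig, augment
from .groundtruth import (DEFAULT_SIGMA, DEFAULT_THRESHOLD, make_attention_map,
                          make_density_map, pool_to_stride)
from .losses import DEFAULT_ALPHA, SSIMConfig, combined_loss
from .metrics import CountRecord, evaluate
from .network import Adam, EarDensityNet, ModelConfig, Tensor, normalize_image
from .network import tiny_config

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass
class TrainConfig:
    """Training hyper-parameters; stated defaults follow the full recipe
    (Adam, initial learning rate 1e-4, loss weight alpha 0.1, 512-px crops,
    attention threshold 0.001, flip/hue probabilities 0.5)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 4
    alpha: float = DEFAULT_ALPHA
    sigma: float = DEFAULT_SIGMA
    th: float = DEFAULT_THRESHOLD
    crops_per_image: int = 4     # random crops drawn per image per epoch
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ssim: SSIMConfig = field(default_factory=SSIMConfig)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimiser is supported")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            d["augmentation"] = AugmentationConfig(**d["augmentation"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        if "ssim" in d and isinstance(d["ssim"], dict):
            d["ssim"] = SSIMConfig(**d["ssim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def smoke_config(**overrides) -> TrainConfig:
    """Reduced desk-scale preset: tiny model, 64-px crops, 5 epochs.

    The learning rate is raised to 1e-3 for this preset — with a model two
    orders of magnitude smaller and only a few hundred updates, the
    full-scale rate would barely move the weights.
    """
    base = dict(model=tiny_config(), epochs=5, learning_rate=1e-3,
                sigma=1.5,
                augmentation=AugmentationConfig(crop_size=64))
    base.update(overrides)
    return TrainConfig(**base)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read an image file as float32 RGB in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    return np.clip(arr, 0.0, 1.0).astype(np.float32)


def load_dataset(data_dir) -> list[tuple[np.ndarray, PointAnnotationSet]]:
    """Load (image, points) pairs from a split directory with points.csv."""
    data_dir = Path(data_dir)
    csv_path = data_dir / "points.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no points.csv in {data_dir}")
    image_paths = sorted(p for p in data_dir.iterdir()
                         if p.suffix.lower() in IMAGE_SUFFIXES)
    if not image_paths:
        raise ValueError(f"no images found in {data_dir}")
    images = {p.name: load_image(p) for p in image_paths}
    first = next(iter(images.values()))
    size = (first.shape[1], first.shape[0])
    anns = read_points(csv_path, image_size=size, image_ids=list(images))
    return [(images[a.image_id], a) for a in anns]


def _ground_truth_batch(point_sets, shape, sigma, th, output_stride):
    den, att = [], []
    for pts in point_sets:
        d = make_density_map(pts, shape, sigma=sigma)
        a = make_attention_map(d, sigma=sigma, th=th)
        if output_stride > 1:
            d = pool_to_stride(d, output_stride)
            # attention stays binary on the coarse grid: active if any
            # constituent pixel was active
            h, w = a.shape
            a = (a.reshape(h // output_stride, output_stride,
                           w // output_stride, output_stride)
                 .max(axis=(1, 3)))
        den.append(d)
        att.append(a)
    return (np.stack(den)[:, None].astype(np.float32),
            np.stack(att)[:, None].astype(np.float32))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: EarDensityNet, path, train_config: TrainConfig | None = None):
    meta = {"model": model.config.to_dict()}
    if train_config is not None:
        meta["sigma"] = train_config.sigma
        meta["th"] = train_config.th
    state = model.state_dict()
    state["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **state)
    return Path(path)


def load_checkpoint(path) -> EarDensityNet:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(state.pop("__meta__")).decode())
    model = EarDensityNet(ModelConfig.from_dict(meta["model"]), rng=0)
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(config: TrainConfig, data_dir, out_dir=None,
          log_callback=None):
    """Train a network on a split directory.

    Returns ``(model, log)`` where ``log`` is a DataFrame with one row per
    step holding the loss components.  If ``out_dir`` is given, a
    ``train_log.csv`` and per-epoch ``checkpoint.npz`` are written there.
    A non-finite loss aborts with a diagnostic.
    """
    dataset = load_dataset(data_dir)
    if not dataset:
        raise ValueError(f"dataset at {data_dir} is empty")
    rng = np.random.default_rng(config.seed)
    model = EarDensityNet(config.model, rng=np.random.default_rng(
        int(rng.integers(0, 2**31 - 1))))
    model.train()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    crop = config.augmentation.crop_size
    os_ = config.model.output_stride
    rows = []
    step = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset)).repeat(config.crops_per_image)
        order = rng.permutation(order)
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            imgs, pts = [], []
            for i in batch_idx:
                image, points = dataset[i]
                image, points = augment(image, points, config.augmentation, rng)
                imgs.append(normalize_image(image).transpose(2, 0, 1))
                pts.append(points)
            x = Tensor(np.stack(imgs))
            gt_den, gt_att = _ground_truth_batch(
                pts, (crop, crop), config.sigma, config.th, os_)
            pair = model(x)
            loss, bd = combined_loss(pair.density, pair.attention,
                                     gt_den, gt_att,
                                     alpha=config.alpha, ssim_config=config.ssim)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"loss={loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            rows.append({"epoch": epoch, "step": step, "l_den": bd.l_den,
                         "l_c": bd.l_c, "l_att": bd.l_att, "total": bd.total})
            if log_callback is not None:
                log_callback(rows[-1])
            step += 1
        if out_dir is not None:
            save_checkpoint(model, out_dir / "checkpoint.npz", config)
    log = pd.DataFrame(rows)
    if out_dir is not None:
        log.to_csv(out_dir / "train_log.csv", index=False)
    model.eval()
    return model, log


def predict_counts(model: EarDensityNet, images: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-image predicted counts (density-map integrals), deterministic."""
    rows = [{"image_id": name, "predicted_count": model.predict_count(img)}
            for name, img in images.items()]
    return pd.DataFrame(rows)


def evaluate_on_split(model: EarDensityNet, data_dir):
    """Run the model over a split and score it against the annotations."""
    dataset = load_dataset(data_dir)
    records = [CountRecord(image_id=pts.image_id,
                           predicted_count=model.predict_count(img),
                           true_count=len(pts))
               for img, pts in dataset]
    return evaluate(records), records


def constant_mean_baseline(train_counts, eval_records) -> float:
    """MAE of always predicting the training-split mean count."""
    mean_count = float(np.mean(list(train_counts)))
    errs = [abs(mean_count - r.true_count) for r in eval_records]
    return float(np.mean(errs))
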