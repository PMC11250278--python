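"""Counting evaluation: MAE, RMSE and MAPE over per-image count records.

    MAE  = (1/N) sum |P_i - G_i|
    RMSE = sqrt((1/N) sum |P_i - G_i|^2)
    MAPE = (100%/N) sum |P_i - G_i| / G_i

where P_i is the predicted count (density-map integral, not rounded) and
G_i the annotated count of image i.  Images with G_i = 0 are excluded from
MAPE with a warning; MAE <= RMSE always (Jensen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation_io import PointAnnotationSet


@dataclass(frozen=True)
class CountRecord:
    image_id: str
    predicted_count: float
    true_count: int

    def __post_init__(self):
        if not np.isfinite(self.predicted_count):
            raise ValueError(f"{self.image_id}: predicted count is not finite")
        if self.true_count < 0:
            raise ValueError(f"{self.image_id}: negative true count")


@dataclass(frozen=True)
class EvalReport:
    n_images: int
    mae: float
    rmse: float
    mape_percent: float | None

    def to_dict(self) -> dict:
        return {"n_images": self.n_images, "mae": self.mae, "rmse": self.rmse,
                "mape_percent": self.mape_percent}


def evaluate(records: Sequence[CountRecord]) -> EvalReport:
    """Compute MAE / RMSE / MAPE for a non-empty list of count records."""
    if len(records) == 0:
        raise ValueError("cannot evaluate an empty record list")
    pred = np.array([r.predicted_count for r in records], dtype=np.float64)
    true = np.array([r.true_count for r in records], dtype=np.float64)
    err = np.abs(pred - true)
    mae = float(err.mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    nonzero = true > 0
    if nonzero.all():
        mape = float(100.0 * (err / true).mean())
    elif nonzero.any():
        warnings.warn(f"MAPE excludes {int((~nonzero).sum())} zero-count image(s)",
                      stacklevel=2)
        mape = float(100.0 * (err[nonzero] / true[nonzero]).mean())
    else:
        raise ValueError("MAPE undefined: every image has a zero true count")
    return EvalReport(n_images=len(records), mae=mae, rmse=rmse, mape_percent=mape)


@dataclass(frozen=True)
class DatasetSummary:
    """Split statistics: image count and min/max/avg/total annotated ears."""

    n_images: int
    min_count: int
    max_count: int
    avg_count: float  # total / n_images, reported to two decimals
    total_count: int


def summarize_counts(counts: Iterable[int]) -> DatasetSummary:
    counts = np.asarray(list(counts), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("cannot summarise an empty split")
    total = int(counts.sum())
    return DatasetSummary(n_images=int(counts.size),
                          min_count=int(counts.min()),
                          max_count=int(counts.max()),
                          avg_count=round(total / counts.size, 2),
                          total_count=total)


def dataset_summary(annotations: Sequence[PointAnnotationSet]) -> DatasetSummary:
    """Summary of a split given its per-image point annotations."""
    return summarize_counts(len(a) for a in annotations)
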