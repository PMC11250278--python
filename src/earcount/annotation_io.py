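"""Reading, writing and converting wheat-ear annotations.

Two CSV dialects are supported for bounding boxes:

``gwhd_csv``
    One row per image with columns ``image_name`` and ``BoxesString``, the
    latter a semicolon-separated list of ``x_min y_min x_max y_max``
    quadruples ("no_box" or an empty field means no ears).  Mirrors the
    public Global Wheat Head Detection layout.

``simple_csv``
    One semicolon-separated row per image: ``image_id; box; box; ...`` with
    each box a space-separated quadruple.

Point annotations (ear centres) use a plain CSV with header
``image_id,x,y``, one row per point.  Coordinates everywhere are
continuous, 0-based, origin at the top-left, x = column, y = row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class AnnotationError(ValueError):
    """Raised for malformed or geometrically invalid annotation data."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise AnnotationError(f"non-finite box coordinates {vals}")
        if min(vals) < 0:
            raise AnnotationError(f"negative box coordinates {vals}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise AnnotationError(f"inverted or degenerate box {vals}")

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def clipped(self, width: float, height: float) -> "BoundingBox":
        return BoundingBox(min(self.x_min, width), min(self.y_min, height),
                           min(self.x_max, width), min(self.y_max, height))


@dataclass
class BoxAnnotationSet:
    """All box annotations of one image."""

    image_id: str
    image_size: tuple[int, int]  # (width, height)
    boxes: list[BoundingBox] = field(default_factory=list)


@dataclass
class PointAnnotationSet:
    """All ear-centre points of one image; ``points`` is an (N, 2) array
    of (x, y) coordinates and N is the ear count."""

    image_id: str
    image_size: tuple[int, int]
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        w, h = self.image_size
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (x < 0).any() or (x >= w).any() or (y < 0).any() or (y >= h).any():
                raise AnnotationError(
                    f"points of {self.image_id!r} outside [0,{w}) x [0,{h})")

    def __len__(self) -> int:
        return len(self.points)


def _parse_box_string(text: str, line_no: int) -> list[BoundingBox]:
    text = text.strip()
    if not text or text.lower() == "no_box":
        return []
    boxes = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split()
        if len(parts) != 4:
            raise AnnotationError(
                f"line {line_no}: box {chunk!r} does not have 4 coordinates")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise AnnotationError(f"line {line_no}: non-numeric box {chunk!r}") from exc
        try:
            boxes.append(BoundingBox(*vals))
        except AnnotationError as exc:
            raise AnnotationError(f"line {line_no}: {exc}") from exc
    return boxes


def read_box_annotations(path, dialect: str = "gwhd_csv",
                         image_size: tuple[int, int] = (1024, 1024),
                         clip: bool = True) -> list[BoxAnnotationSet]:
    """Parse a box-annotation CSV into one BoxAnnotationSet per image row.

    ``clip`` clips boxes extending past the image bounds (count-preserving);
    boxes that are inverted or negative raise :class:`AnnotationError` with
    the offending line number.
    """
    path = Path(path)
    if dialect == "gwhd_csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("image_name", "BoxesString"):
            if col not in frame.columns:
                raise AnnotationError(f"{path}: missing column {col!r}")
        rows = [(str(r.image_name), str(r.BoxesString), i + 2)
                for i, r in enumerate(frame.itertuples(index=False))]
    elif dialect == "simple_csv":
        rows = []
        with open(path, newline="") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                image_id, _, rest = line.partition(";")
                rows.append((image_id.strip(), rest, i))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out = []
    w, h = image_size
    for image_id, box_text, line_no in rows:
        boxes = _parse_box_string(box_text, line_no)
        if clip:
            boxes = [b.clipped(w, h) for b in boxes]
        else:
            for b in boxes:
                if b.x_max > w or b.y_max > h:
                    raise AnnotationError(
                        f"line {line_no}: box exceeds the {w}x{h} image")
        out.append(BoxAnnotationSet(image_id=image_id, image_size=(w, h), boxes=boxes))
    return out


def boxes_to_points(annotations: BoxAnnotationSet) -> PointAnnotationSet:
    """Centroid of each box becomes one ear-centre point (order preserved)."""
    w, h = annotations.image_size
    pts = []
    for box in annotations.boxes:
        cx, cy = box.centroid
        # a box flush with the right/bottom edge has its centroid inside
        pts.append((min(cx, np.nextafter(float(w), 0.0)),
                    min(cy, np.nextafter(float(h), 0.0))))
    points = np.array(pts, dtype=np.float64).reshape(-1, 2)
    return PointAnnotationSet(image_id=annotations.image_id,
                              image_size=annotations.image_size, points=points)


def write_points(annotation_sets, path):
    """Write point sets to CSV (header ``image_id,x,y``, one row per point)."""
    if isinstance(annotation_sets, PointAnnotationSet):
        annotation_sets = [annotation_sets]
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y"])
        for ann in annotation_sets:
            for x, y in ann.points:
                writer.writerow([ann.image_id, repr(float(x)), repr(float(y))])
    return path


def read_points(path, image_size: tuple[int, int],
                image_ids=None) -> list[PointAnnotationSet]:
    """Read a points CSV back into PointAnnotationSets (grouped by image).

    ``image_ids`` optionally fixes the set and order of images, so images
    with zero points survive the round trip.
    """
    frame = pd.read_csv(path, dtype={"image_id": str, "x": float, "y": float})
    for col in ("image_id", "x", "y"):
        if col not in frame.columns:
            raise AnnotationError(f"{path}: missing column {col!r}")
    grouped = {k: g[["x", "y"]].to_numpy(dtype=np.float64)
               for k, g in frame.groupby("image_id", sort=False)}
    ids = list(image_ids) if image_ids is not None else list(grouped)
    return [PointAnnotationSet(image_id=i, image_size=image_size,
                               points=grouped.get(i, np.empty((0, 2))))
            for i in ids]
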