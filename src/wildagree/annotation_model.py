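"""Core data types for multi-observer wildlife image annotation.

Coordinates are 0-based with the origin at the image top-left; a box with
top-left corner (x, y), width w and height h spans the half-open region
[x, x+w) x [y, y+h).  All geometry downstream (median boxes, IOU, tiling)
uses this convention.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["observer_id", "image_id", "x", "y", "w", "h", "label"]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner (x, y), width w, height h, in pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"box origin must be non-negative, got ({self.x}, {self.y})")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.w, self.h)

    def clip(self, width: float, height: float) -> "BoundingBox | None":
        """Clip to [0, width) x [0, height); None if nothing remains."""
        x1 = max(self.x, 0.0)
        y1 = max(self.y, 0.0)
        x2 = min(self.x2, width)
        y2 = min(self.y2, height)
        if x2 <= x1 or y2 <= y1:
            return None
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)


GEOMETRY_BOX = "box"
GEOMETRY_POLYGON_ENVELOPE = "polygon-envelope"


@dataclass(frozen=True)
class Annotation:
    """One observer's box and class label for one image."""

    observer_id: str
    image_id: str
    box: BoundingBox
    label: str
    geometry_kind: str = GEOMETRY_BOX

    def with_label(self, label: str) -> "Annotation":
        return replace(self, label=label)


@dataclass(frozen=True)
class ImageMeta:
    """Image dimensions plus optional acquisition metadata."""

    image_id: str
    width: int
    height: int
    resolution_cm_px: float | None = None
    agl_m: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)


class ClassScheme:
    """Closed label scheme mapping fine classes to morphological classes.

    Both fine-class names (e.g. species) and morphological names
    (duck/goose/crane/gull/other) are valid labels; morphological names map
    to themselves, so collapsing is idempotent.
    """

    def __init__(
        self,
        fine_classes: Sequence[str],
        morph_map: Mapping[str, str],
        morph_classes: Sequence[str] | None = None,
    ) -> None:
        self.fine_classes = list(fine_classes)
        missing = [c for c in self.fine_classes if c not in morph_map]
        if missing:
            raise ValueError(f"fine classes without a morphological mapping: {missing}")
        self.morph_map = dict(morph_map)
        if morph_classes is None:
            seen: list[str] = []
            for c in self.fine_classes:
                m = self.morph_map[c]
                if m not in seen:
                    seen.append(m)
            morph_classes = seen
        self.morph_classes = list(morph_classes)
        unknown = set(self.morph_map.values()) - set(self.morph_classes)
        if unknown:
            raise ValueError(f"morph_map targets outside morph_classes: {sorted(unknown)}")

    def is_valid(self, label: str) -> bool:
        return label in self.morph_map or label in self.morph_classes

    def to_morphology(self, label: str) -> str:
        if label in self.morph_classes:
            return label
        try:
            return self.morph_map[label]
        except KeyError:
            raise KeyError(f"label {label!r} is not in the class scheme") from None

    def at_level(self, label: str, level: str) -> str:
        """Project a label to 'fine' (identity) or 'morphological'."""
        if level == "fine":
            return label
        if level == "morphological":
            return self.to_morphology(label)
        raise ValueError(f"unknown level {level!r}; expected 'fine' or 'morphological'")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassScheme":
        with open(path) as fh:
            data = json.load(fh)
        return cls(data["fine_classes"], data["morph_map"], data.get("morph_classes"))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "fine_classes": self.fine_classes,
                    "morph_map": self.morph_map,
                    "morph_classes": self.morph_classes,
                },
                fh,
                indent=1,
            )


def waterfowl_scheme() -> ClassScheme:
    """Twelve-species waterfowl scheme with duck/goose/crane/gull/other morphology."""
    morph_map = {
        "Mallard": "duck",
        "Northern Pintail": "duck",
        "American Wigeon": "duck",
        "Teal": "duck",
        "Gadwall": "duck",
        "Northern Shoveler": "duck",
        "Ringneck": "duck",
        "Redhead": "duck",
        "Ruddy Duck": "duck",
        "Canada Goose": "goose",
        "Snow Goose": "goose",
        "Sandhill Crane": "crane",
        "Other": "other",
    }
    return ClassScheme(
        fine_classes=list(morph_map),
        morph_map=morph_map,
        morph_classes=["duck", "goose", "crane", "gull", "other"],
    )


def morphology_scheme() -> ClassScheme:
    """Morphology-only scheme used when observers label at the coarse level."""
    classes = ["duck", "goose", "crane", "gull", "other"]
    return ClassScheme(classes, {c: c for c in classes}, classes)


def polygon_envelope(vertices: Sequence[tuple[float, float]]) -> BoundingBox:
    """Axis-aligned envelope of a polygon's vertices."""
    xs = [v[0] for v in vertices]
    ys = [v[1] for v in vertices]
    return BoundingBox(min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))


def read_annotations(
    path: str | Path,
    format: str = "csv",
    scheme: ClassScheme | None = None,
) -> list[Annotation]:
    """Read annotations from CSV or COCO-style JSON.

    Records with labels outside the scheme are dropped with a logged warning;
    malformed geometry raises, naming the offending record.
    """
    if format == "csv":
        records = _read_csv(path)
    elif format == "coco-json":
        records = _read_coco(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'coco-json'")

    annotations: list[Annotation] = []
    rejected = 0
    for i, ann in enumerate(records):
        if scheme is not None and not scheme.is_valid(ann.label):
            logger.warning("record %d: unknown label %r rejected", i, ann.label)
            rejected += 1
            continue
        annotations.append(ann)
    if rejected:
        logger.warning("rejected %d of %d records with labels outside the scheme",
                       rejected, len(records))
    return annotations


def _read_csv(path: str | Path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(CSV_COLUMNS) <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns {CSV_COLUMNS}")
        for i, row in enumerate(reader):
            try:
                box = BoundingBox(float(row["x"]), float(row["y"]),
                                  float(row["w"]), float(row["h"]))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed geometry in row {i + 1}: {exc}") from exc
            out.append(Annotation(row["observer_id"], row["image_id"], box, row["label"]))
    return out


def _read_coco(path: str | Path) -> list[Annotation]:
    with open(path) as fh:
        data = json.load(fh)
    categories = {c["id"]: c["name"] for c in data.get("categories", [])}
    images = {im["id"]: im for im in data.get("images", [])}
    out: list[Annotation] = []
    for rec in data.get("annotations", []):
        rec_id = rec.get("id", "?")
        image = images.get(rec["image_id"], {})
        image_id = str(image.get("file_name", rec["image_id"]))
        observer = str(rec.get("observer_id", rec.get("attributes", {}).get("observer_id", "")))
        label = categories.get(rec.get("category_id"), str(rec.get("category_id")))
        seg = rec.get("segmentation")
        try:
            if seg:
                flat = seg[0] if isinstance(seg[0], (list, tuple)) else seg
                verts = list(zip(flat[0::2], flat[1::2]))
                box = polygon_envelope(verts)
                kind = GEOMETRY_POLYGON_ENVELOPE
            else:
                x, y, w, h = rec["bbox"]
                box = BoundingBox(float(x), float(y), float(w), float(h))
                kind = GEOMETRY_BOX
        except (KeyError, ValueError, IndexError, TypeError) as exc:
            raise ValueError(f"annotation id {rec_id}: malformed geometry: {exc}") from exc
        out.append(Annotation(observer, image_id, box, label, kind))
    return out


def write_annotations(
    path: str | Path,
    annotations: Iterable[Annotation],
    format: str = "csv",
    images: Sequence[ImageMeta] | None = None,
) -> None:
    annotations = list(annotations)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for a in annotations:
                writer.writerow([a.observer_id, a.image_id,
                                 a.box.x, a.box.y, a.box.w, a.box.h, a.label])
    elif format == "coco-json":
        image_ids = sorted({a.image_id for a in annotations})
        meta_by_id = {m.image_id: m for m in images or []}
        image_index = {im: i + 1 for i, im in enumerate(image_ids)}
        labels = sorted({a.label for a in annotations})
        cat_index = {lab: i + 1 for i, lab in enumerate(labels)}
        doc = {
            "images": [
                {
                    "id": image_index[im],
                    "file_name": im,
                    **(
                        {"width": meta_by_id[im].width, "height": meta_by_id[im].height}
                        if im in meta_by_id else {}
                    ),
                }
                for im in image_ids
            ],
            "categories": [{"id": cat_index[lab], "name": lab} for lab in labels],
            "annotations": [
                {
                    "id": i + 1,
                    "image_id": image_index[a.image_id],
                    "category_id": cat_index[a.label],
                    "bbox": [a.box.x, a.box.y, a.box.w, a.box.h],
                    "area": a.box.area,
                    "observer_id": a.observer_id,
                    "iscrowd": 0,
                }
                for i, a in enumerate(annotations)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def collapse_to_morphology(
    annotations: Iterable[Annotation], scheme: ClassScheme
) -> list[Annotation]:
    """Replace fine (species) labels by their morphological class.

    Boxes, ids and ordering are unchanged; morphological labels pass through,
    so the operation is idempotent.
    """
    return [a.with_label(scheme.to_morphology(a.label)) for a in annotations]


def tile_grid(meta: ImageMeta, tile_w: int, tile_h: int) -> list[ImageMeta]:
    """Row-major, non-overlapping tile grid covering the image.

    The number of rows/columns is the rounded ratio of image to tile size, so
    a trailing remainder smaller than half a tile is absorbed into the last
    row/column (clipped or extended to the image edge) instead of forming a
    sliver tile; a 5472 x 3648 image with 684 x 521 tiles yields the 8 x 7 = 56
    tile layout.  Every pixel belongs to exactly one tile.
    """
    if tile_w <= 0 or tile_h <= 0:
        raise ValueError("tile dimensions must be positive")
    if tile_w >= meta.width and tile_h >= meta.height:
        if tile_w > meta.width or tile_h > meta.height:
            logger.warning("tile %dx%d larger than image %dx%d; using a single tile",
                           tile_w, tile_h, meta.width, meta.height)
        return [replace(meta, image_id=f"{meta.image_id}_r0_c0")]
    ncols = max(1, round(meta.width / tile_w))
    nrows = max(1, round(meta.height / tile_h))
    tiles: list[ImageMeta] = []
    for r in range(nrows):
        for c in range(ncols):
            x0 = c * tile_w
            y0 = r * tile_h
            w = (meta.width - x0) if c == ncols - 1 else tile_w
            h = (meta.height - y0) if r == nrows - 1 else tile_h
            tiles.append(
                ImageMeta(f"{meta.image_id}_r{r}_c{c}", int(w), int(h),
                          meta.resolution_cm_px, meta.agl_m)
            )
    return tiles


def tile_image(
    meta: ImageMeta,
    tile_w: int,
    tile_h: int,
    annotations: Iterable[Annotation] = (),
) -> list[tuple[ImageMeta, list[Annotation]]]:
    """Slice an image frame into tiles and reassign annotations.

    Each annotation goes to the tile containing its box center; coordinates
    are translated into the tile-local frame and clipped to the tile, so the
    multiset of annotations is conserved across tiles.
    """
    tiles = tile_grid(meta, tile_w, tile_h)
    ncols = max(1, round(meta.width / tile_w)) if tile_w < meta.width else 1
    nrows = len(tiles) // ncols
    assigned: dict[str, list[Annotation]] = {t.image_id: [] for t in tiles}
    origin: dict[str, tuple[int, int]] = {}
    by_id: dict[str, ImageMeta] = {}
    for t in tiles:
        r, c = _parse_tile_rc(t.image_id)
        origin[t.image_id] = (c * tile_w, r * tile_h)
        by_id[t.image_id] = t
    for ann in annotations:
        if ann.image_id != meta.image_id:
            raise ValueError(f"annotation references {ann.image_id!r}, not {meta.image_id!r}")
        cx, cy = ann.box.center
        c = min(int(cx // tile_w), ncols - 1)
        r = min(int(cy // tile_h), nrows - 1)
        tid = f"{meta.image_id}_r{r}_c{c}"
        x0, y0 = origin[tid]
        tmeta = by_id[tid]
        lx, ly = ann.box.x - x0, ann.box.y - y0
        # center inside the tile guarantees a non-empty clipped region
        x1, y1 = max(lx, 0.0), max(ly, 0.0)
        x2 = min(lx + ann.box.w, float(tmeta.width))
        y2 = min(ly + ann.box.h, float(tmeta.height))
        clipped = BoundingBox(x1, y1, x2 - x1, y2 - y1)
        assigned[tid].append(replace(ann, image_id=tid, box=clipped))
    return [(t, assigned[t.image_id]) for t in tiles]


def _parse_tile_rc(tile_id: str) -> tuple[int, int]:
    stem = tile_id.rsplit("_r", 1)[1]
    r, c = stem.split("_c")
    return int(r), int(c)
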