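"""Image-attribute covariates for aggregate annotations.

Two families of covariates are computed per aggregate annotation: geometric
context (box size relative to the image, neighbor counts, distance from the
image center, class composition) and gray-level co-occurrence matrix (GLCM)
texture summaries of the box interior, of a "donut" transition zone around
the box, and of their difference.

GLCM features follow the standard definitions (contrast, dissimilarity,
homogeneity, energy) on a symmetric, normalized co-occurrence matrix of
intensities quantized to 32 gray levels, averaged over pixel offsets 1, 3
and 5 at eight 45-degree angles.  Co-occurrence counting honors an
arbitrary pixel mask so that the ring-shaped donut region is handled
exactly rather than approximated by a rectangle.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aggregation import AggregateAnnotation, NO_CONSENSUS
from .annotation_model import BoundingBox, ImageMeta

GLCM_FEATURES = ("contrast", "energy", "dissimilarity", "homogeneity")
DEFAULT_OFFSETS = (1, 3, 5)
DEFAULT_LEVELS = 32

# eight 45-degree angles; pixel offsets are round(d*sin), round(d*cos),
# the convention co-occurrence implementations use for diagonal distances
_ANGLES = [k * math.pi / 4 for k in range(8)]


def _offsets_for(distance: int) -> list[tuple[int, int]]:
    return [
        (round(math.sin(a) * distance), round(math.cos(a) * distance)) for a in _ANGLES
    ]


def geometry_covariates(
    aggregate: AggregateAnnotation,
    image_aggregates: Sequence[AggregateAnnotation],
    meta: ImageMeta,
    dataset_aggregates: Sequence[AggregateAnnotation] | None = None,
) -> dict[str, float]:
    """Geometric and contextual covariates for one aggregate annotation.

    Neighbor, density, same-class and rarity counts all exclude the focal
    annotation itself.  The neighbor radius is twice the larger of the box's
    width and height.
    """
    box = aggregate.box
    others = [a for a in image_aggregates if a is not aggregate]
    cx, cy = box.center
    radius = 2.0 * max(box.w, box.h)
    n_neighbors = sum(
        1
        for a in others
        if math.dist((cx, cy), a.box.center) <= radius
    )
    icx, icy = meta.center
    out = {
        "area": box.area,
        "bbox_percent_area": 100.0 * box.area / (meta.width * meta.height),
        "n_neighbors": float(n_neighbors),
        "distance_from_center": math.dist((cx, cy), (icx, icy)),
        "density": float(len(others)),
    }
    if aggregate.has_consensus and others:
        same = sum(1 for a in others if a.consensus_class == aggregate.consensus_class)
        out["same_class_percent"] = 100.0 * same / len(others)
    if dataset_aggregates is not None and aggregate.has_consensus:
        pool = [a for a in dataset_aggregates if a is not aggregate]
        if pool:
            same = sum(1 for a in pool if a.consensus_class == aggregate.consensus_class)
            out["rarity"] = 100.0 * same / len(pool)
    if meta.resolution_cm_px is not None:
        out["spatial_resolution"] = meta.resolution_cm_px
    if meta.agl_m is not None:
        out["agl"] = meta.agl_m
    return out


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma for RGB input; identity for 2-D input.  Returns floats."""
    image = np.asarray(image)
    if image.ndim == 3:
        rgb = image[..., :3].astype(float)
        return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    if image.ndim == 2:
        return image.astype(float)
    raise ValueError(f"expected 2-D or 3-D image, got shape {image.shape}")


def quantize(gray: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Quantize intensities in [0, 255] to integer bins 0..levels-1."""
    g = np.clip(np.asarray(gray, dtype=float), 0.0, 255.0)
    return np.minimum((g / 256.0 * levels).astype(np.intp), levels - 1)


def glcm_features(
    region: np.ndarray,
    mask: np.ndarray | None = None,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    levels: int = DEFAULT_LEVELS,
) -> dict[str, float]:
    """GLCM texture summary of a (possibly masked) image region.

    For each offset d and each of the eight 45-degree directions, a
    symmetric co-occurrence matrix of quantized gray levels is accumulated
    over pixel pairs lying inside the mask, then normalized.  The returned
    value per feature is the mean over all offset-direction combinations
    that produced at least one pair.
    """
    gray = to_grayscale(region)
    if gray.size <= 1 or min(gray.shape) < 1 or gray.shape[0] * gray.shape[1] < 2:
        raise ValueError("region must contain at least 2 pixels")
    q = quantize(gray, levels)
    if mask is None:
        mask = np.ones(q.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != q.shape:
            raise ValueError("mask shape must match region shape")
        if mask.sum() < 2:
            raise ValueError("mask must select at least 2 pixels")

    i_idx, j_idx = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    diff2 = (i_idx - j_idx) ** 2
    absdiff = np.abs(i_idx - j_idx)

    per_combo: dict[str, list[float]] = {f: [] for f in GLCM_FEATURES}
    h, w = q.shape
    for d in offsets:
        for drr, dcc in _offsets_for(d):
            r0, r1 = max(0, -drr), min(h, h - drr)
            c0, c1 = max(0, -dcc), min(w, w - dcc)
            if r0 >= r1 or c0 >= c1:
                continue
            src = q[r0:r1, c0:c1]
            dst = q[r0 + drr : r1 + drr, c0 + dcc : c1 + dcc]
            valid = mask[r0:r1, c0:c1] & mask[r0 + drr : r1 + drr, c0 + dcc : c1 + dcc]
            if not valid.any():
                continue
            P = np.zeros((levels, levels))
            np.add.at(P, (src[valid], dst[valid]), 1.0)
            P = P + P.T  # symmetric accumulation
            P /= P.sum()
            per_combo["contrast"].append(float((P * diff2).sum()))
            per_combo["dissimilarity"].append(float((P * absdiff).sum()))
            per_combo["homogeneity"].append(float((P / (1.0 + diff2)).sum()))
            per_combo["energy"].append(float(np.sqrt((P**2).sum())))
    if not per_combo["contrast"]:
        raise ValueError("no valid pixel pairs for any offset/direction")
    return {f: float(np.mean(v)) for f, v in per_combo.items()}


def donut_region(
    box: BoundingBox, meta: ImageMeta, buffer: int = 20
) -> np.ndarray:
    """Boolean mask of the transition zone around a box.

    The mask is the box expanded by ``buffer`` pixels on every side minus
    the box shrunk by ``buffer`` on every side, both clipped to the image.
    When the box is too small to shrink (width or height <= 2*buffer) the
    interior hole degenerates and the mask is the whole expanded box.
    """
    outer = BoundingBox(
        max(box.x - buffer, 0.0),
        max(box.y - buffer, 0.0),
        min(box.x2 + buffer, meta.width) - max(box.x - buffer, 0.0),
        min(box.y2 + buffer, meta.height) - max(box.y - buffer, 0.0),
    )
    if box.clip(meta.width, meta.height) is None:
        raise ValueError("box lies entirely outside the image")
    mask = np.zeros((meta.height, meta.width), dtype=bool)
    mask[int(outer.y) : int(round(outer.y2)), int(outer.x) : int(round(outer.x2))] = True
    if box.w > 2 * buffer and box.h > 2 * buffer:
        ix1, iy1 = int(box.x + buffer), int(box.y + buffer)
        ix2, iy2 = int(round(box.x2 - buffer)), int(round(box.y2 - buffer))
        ix1, iy1 = max(ix1, 0), max(iy1, 0)
        ix2, iy2 = min(ix2, meta.width), min(iy2, meta.height)
        mask[iy1:iy2, ix1:ix2] = False
    return mask


def glcm_difference(
    box_features: Mapping[str, float], donut_features: Mapping[str, float]
) -> dict[str, float]:
    """Elementwise box-minus-donut texture difference."""
    if set(box_features) != set(donut_features):
        raise ValueError(
            f"feature keys differ: {sorted(box_features)} vs {sorted(donut_features)}"
        )
    return {k: box_features[k] - donut_features[k] for k in box_features}


def covariate_record(
    aggregate: AggregateAnnotation,
    image_aggregates: Sequence[AggregateAnnotation],
    meta: ImageMeta,
    image: np.ndarray | None = None,
    dataset_aggregates: Sequence[AggregateAnnotation] | None = None,
    buffer: int = 20,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    levels: int = DEFAULT_LEVELS,
) -> dict[str, float]:
    """Assemble the full covariate vector for one aggregate annotation.

    GLCM covariates are included only when the pixel image is supplied.
    Keys are prefixed ``glcm_box_``, ``glcm_donut_`` and ``glcm_diff_``.
    """
    rec = geometry_covariates(aggregate, image_aggregates, meta, dataset_aggregates)
    if image is not None:
        clipped = aggregate.box.clip(meta.width, meta.height)
        if clipped is None:
            raise ValueError("aggregate box lies outside the image")
        y1, y2 = int(clipped.y), max(int(round(clipped.y2)), int(clipped.y) + 2)
        x1, x2 = int(clipped.x), max(int(round(clipped.x2)), int(clipped.x) + 2)
        box_feats = glcm_features(image[y1:y2, x1:x2], offsets=offsets, levels=levels)
        mask = donut_region(aggregate.box, meta, buffer=buffer)
        donut_feats = glcm_features(image, mask=mask, offsets=offsets, levels=levels)
        diff = glcm_difference(box_feats, donut_feats)
        for name, feats in (("box", box_feats), ("donut", donut_feats), ("diff", diff)):
            for k, v in feats.items():
                rec[f"glcm_{name}_{k}"] = v
    return rec


def class_dummies(
    aggregates: Sequence[AggregateAnnotation],
    reference_class: str | None = None,
) -> "pd.DataFrame":
    """0/1 indicator columns for consensus classes, dropping a reference level.

    The reference level defaults to the most frequent class.  Aggregates
    without a consensus are all-zero rows (they are excluded from model
    fitting anyway).
    """
    import pandas as pd

    labels = [a.consensus_class for a in aggregates]
    decided = [l for l in labels if l != NO_CONSENSUS]
    if not decided:
        return pd.DataFrame(index=range(len(labels)))
    if reference_class is None:
        counts = pd.Series(decided).value_counts()
        reference_class = counts.index[0]
    classes = sorted(set(decided) - {reference_class})
    data = {f"class_{c}": [float(l == c) for l in labels] for c in classes}
    return pd.DataFrame(data)
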