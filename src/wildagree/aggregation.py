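"""Consensus aggregation of redundant annotations.

Redundant boxes drawn by many observers around the same animal are grouped
with DBSCAN on the Euclidean distance between box centers (defaults: radius
eps = 15 px, minimum cluster size 5, the point itself included).  Each
cluster becomes one aggregate annotation: the coordinate-wise median box,
the plurality (mode) class of the member votes, and the IOU of every member
box against the aggregate box.  Boxes that fall outside every cluster are
discarded as noise; clusters whose vote is tied carry no consensus class.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .annotation_model import Annotation, BoundingBox, ClassScheme

NO_CONSENSUS = "NO_CONSENSUS"


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters: neighborhood radius (px) and minimum cluster size.

    ``min_size`` counts the point itself: a core point has at least
    ``min_size`` centers (including its own) within ``epsilon``.
    """

    epsilon: float = 15.0
    min_size: int = 5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_size < 1:
            raise ValueError("min_size must be at least 1")


@dataclass
class Cluster:
    image_id: str
    members: list[Annotation]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AggregateAnnotation:
    """Consensus annotation for one cluster of redundant boxes."""

    image_id: str
    box: BoundingBox
    vote_tally: dict[str, int]
    consensus_class: str
    member_ious: list[float]
    members: list[Annotation]
    morph_fallback: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def has_consensus(self) -> bool:
        return self.consensus_class != NO_CONSENSUS


@dataclass
class AggregationResult:
    """Aggregates plus the noise annotations that no cluster claimed."""

    aggregates: list[AggregateAnnotation]
    discarded: list[Annotation]
    n_input: int

    @property
    def no_consensus_count(self) -> int:
        return sum(1 for a in self.aggregates if not a.has_consensus)

    @property
    def usable(self) -> list[AggregateAnnotation]:
        return [a for a in self.aggregates if a.has_consensus]

    def summary(self) -> dict[str, float]:
        return aggregation_summary(
            n_input=self.n_input,
            n_discarded=len(self.discarded),
            n_aggregates=len(self.aggregates),
            n_no_consensus=self.no_consensus_count,
        )


def aggregation_summary(
    n_input: int, n_discarded: int, n_aggregates: int, n_no_consensus: int
) -> dict[str, float]:
    """Headline pipeline accounting: discard and no-consensus rates.

    Percentages are fractions of, respectively, the raw annotation count and
    the aggregate count; ``usable_total`` is the number of aggregates that
    reached a plurality class vote.
    """
    return {
        "n_input": n_input,
        "n_discarded": n_discarded,
        "n_aggregates": n_aggregates,
        "n_no_consensus": n_no_consensus,
        "discard_percent": 100.0 * n_discarded / n_input if n_input else 0.0,
        "no_consensus_percent": (
            100.0 * n_no_consensus / n_aggregates if n_aggregates else 0.0
        ),
        "usable_total": n_aggregates - n_no_consensus,
    }


def _sorted_for_determinism(annotations: Iterable[Annotation]) -> list[Annotation]:
    # DBSCAN border points reachable from two clusters go to whichever cluster
    # scans them first; sorting fixes that order.
    return sorted(annotations, key=lambda a: (a.observer_id, a.box.x, a.box.y))


def cluster_boxes(
    annotations: Sequence[Annotation], params: ClusterParams = ClusterParams()
) -> tuple[list[Cluster], list[Annotation]]:
    """DBSCAN on box centers for the annotations of a single image.

    Returns (clusters, noise); together they partition the input.  Clusters
    are ordered by their first member in the deterministic scan order.
    """
    annotations = list(annotations)
    if not annotations:
        return [], []
    image_ids = {a.image_id for a in annotations}
    if len(image_ids) != 1:
        raise ValueError(f"cluster_boxes expects one image, got {sorted(image_ids)}")
    ordered = _sorted_for_determinism(annotations)
    centers = np.array([a.box.center for a in ordered])
    labels = DBSCAN(eps=params.epsilon, min_samples=params.min_size).fit_predict(centers)
    clusters: dict[int, Cluster] = {}
    noise: list[Annotation] = []
    order: list[int] = []
    for ann, lab in zip(ordered, labels):
        if lab < 0:
            noise.append(ann)
            continue
        if lab not in clusters:
            clusters[lab] = Cluster(ann.image_id, [])
            order.append(lab)
        clusters[lab].members.append(ann)
    return [clusters[lab] for lab in order], noise


def estimate_epsilon(annotations: Sequence[Annotation], k: int = 5) -> float:
    """Knee of the sorted k-th-nearest-neighbor distance curve over box centers.

    The curve (rank, distance), normalized to the unit square, is compared to
    the chord joining its endpoints; the knee is the point of maximum
    perpendicular distance.  Intended as an aid for choosing the DBSCAN
    radius, not a fixed rule.
    """
    annotations = list(annotations)
    if len(annotations) < k + 1:
        raise ValueError(f"need at least {k + 1} annotations for k={k}")
    centers = np.array([a.box.center for a in annotations])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(centers)
    dists, _ = nn.kneighbors(centers)
    kdist = np.sort(dists[:, k])
    n = len(kdist)
    span = kdist[-1] - kdist[0]
    if span <= 0 or n < 3:
        return float(kdist[0])
    x = np.linspace(0.0, 1.0, n)
    y = (kdist - kdist[0]) / span
    # perpendicular distance to the chord from (0, y0) to (1, y1)
    perp = np.abs(y - x * (y[-1] - y[0]) - y[0]) / np.sqrt(1 + (y[-1] - y[0]) ** 2)
    return float(kdist[int(np.argmax(perp))])


def compute_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes under the half-open convention."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def aggregate_cluster(
    cluster: Cluster, scheme: ClassScheme, level: str = "morphological"
) -> AggregateAnnotation:
    """Median box, plurality class, and member IOUs for one cluster.

    The aggregate box takes the median of each coordinate (x, y, w, h) over
    the members (mean of the two central order statistics for even counts).
    The consensus class is the unique plurality of the votes at the requested
    level; a tie yields NO_CONSENSUS.  A species-level tie whose tied classes
    all share one morphological class records that class as a fallback.
    """
    if not cluster.members:
        raise ValueError("cannot aggregate an empty cluster")
    coords = np.array([[m.box.x, m.box.y, m.box.w, m.box.h] for m in cluster.members])
    med = np.median(coords, axis=0)
    box = BoundingBox(*med)
    tally = Counter(scheme.at_level(m.label, level) for m in cluster.members)
    top = max(tally.values())
    winners = sorted(c for c, n in tally.items() if n == top)
    fallback = None
    if len(winners) == 1:
        consensus = winners[0]
    else:
        consensus = NO_CONSENSUS
        if level == "fine":
            morphs = {scheme.to_morphology(c) for c in winners}
            if len(morphs) == 1:
                fallback = morphs.pop()
    ious = [compute_iou(m.box, box) for m in cluster.members]
    return AggregateAnnotation(
        image_id=cluster.image_id,
        box=box,
        vote_tally=dict(tally),
        consensus_class=consensus,
        member_ious=ious,
        members=list(cluster.members),
        morph_fallback=fallback,
    )


def aggregate_annotation_set(
    annotations: Sequence[Annotation],
    params: ClusterParams = ClusterParams(),
    scheme: ClassScheme | None = None,
    level: str = "morphological",
) -> AggregationResult:
    """Cluster and aggregate annotations image by image.

    Clustering never crosses image frames; the result conserves the input
    (every annotation ends up in exactly one aggregate or in ``discarded``).
    """
    if scheme is None:
        raise ValueError("a ClassScheme is required")
    annotations = list(annotations)
    by_image: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_image.setdefault(a.image_id, []).append(a)
    aggregates: list[AggregateAnnotation] = []
    discarded: list[Annotation] = []
    for image_id in sorted(by_image):
        clusters, noise = cluster_boxes(by_image[image_id], params)
        discarded.extend(noise)
        for cl in clusters:
            aggregates.append(aggregate_cluster(cl, scheme, level))
    return AggregationResult(aggregates=aggregates, discarded=discarded,
                             n_input=len(annotations))


def _annotation_to_dict(a: Annotation) -> dict:
    return {
        "observer_id": a.observer_id,
        "image_id": a.image_id,
        "bbox": [a.box.x, a.box.y, a.box.w, a.box.h],
        "label": a.label,
        "geometry_kind": a.geometry_kind,
    }


def _annotation_from_dict(d: Mapping) -> Annotation:
    x, y, w, h = d["bbox"]
    return Annotation(d["observer_id"], d["image_id"], BoundingBox(x, y, w, h),
                      d["label"], d.get("geometry_kind", "box"))


def write_aggregation(path: str | Path, result: AggregationResult) -> None:
    """Serialize a full aggregation result (aggregates, members, noise) to JSON."""
    doc = {
        "n_input": result.n_input,
        "summary": result.summary(),
        "aggregates": [
            {
                "image_id": a.image_id,
                "bbox": [a.box.x, a.box.y, a.box.w, a.box.h],
                "vote_tally": a.vote_tally,
                "consensus_class": a.consensus_class,
                "morph_fallback": a.morph_fallback,
                "member_ious": a.member_ious,
                "members": [_annotation_to_dict(m) for m in a.members],
            }
            for a in result.aggregates
        ],
        "discarded": [_annotation_to_dict(a) for a in result.discarded],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_aggregation(path: str | Path) -> AggregationResult:
    with open(path) as fh:
        doc = json.load(fh)
    aggregates = []
    for rec in doc["aggregates"]:
        x, y, w, h = rec["bbox"]
        aggregates.append(
            AggregateAnnotation(
                image_id=rec["image_id"],
                box=BoundingBox(x, y, w, h),
                vote_tally={k: int(v) for k, v in rec["vote_tally"].items()},
                consensus_class=rec["consensus_class"],
                member_ious=[float(v) for v in rec["member_ious"]],
                members=[_annotation_from_dict(m) for m in rec["members"]],
                morph_fallback=rec.get("morph_fallback"),
            )
        )
    return AggregationResult(
        aggregates=aggregates,
        discarded=[_annotation_from_dict(a) for a in doc["discarded"]],
        n_input=int(doc["n_input"]),
    )
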